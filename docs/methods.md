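# Methods

## Scope and model

`solvkb` quantifies how a two-component solvent (water `w` + cosolvent `c`)
organises around a solute of arbitrary shape, and converts that structure
into the thermodynamics of cosolvent-modulated conformational equilibria.
The chain of quantities is:

1. **Minimum-distance events.** For each solvent molecule in a frame, the
   smallest distance r between any of its atoms and any solute atom, under
   the minimum-image convention in an orthorhombic box. This coordinate
   (rather than a centre-of-mass pair distance) is what makes the analysis
   shape-agnostic: it is well defined for compact and for highly extended
   solutes alike.
2. **MDDF.** The distribution of those minima, normalized by a numerically
   generated ideal reference, `MDDF(r) = n_s(r)/n_s*(r)`.
3. **Finite-volume Kirkwood–Buff integral.**
   `G_ps(R) = (1/ρ_s)[N_ps(R) − N_ps*(R)]`, the excess volume occupied by
   species s within minimum distance R of the solute; its large-R plateau is
   the KBI.
4. **Preferential interaction.** `Γ_pc = ρ_c[G_pc(R) − G_pw(R)]`: the excess
   number of cosolvent molecules in the solute domain relative to bulk
   composition. Γ > 0 is accumulation (urea-like), Γ < 0 preferential
   hydration (TMAO-like).
5. **Wyman linkage.** `ΔΓ = Γ^U − Γ^N = ∂lnK/∂ln a_c` for a two-state
   equilibrium N ⇌ U; positive ΔΓ means the cosolvent favors U.
6. **Transfer free energy.** For a fixed conformation,
   `Δμ_p,tr(m) = ∫₀^m (∂μ_p/∂m_c) dm_c` with the integrand
   `−Γ_pc·R·T·(M_p/M_c)·(1/m_c + ∂lnγ_c/∂m_c)`; the U−N difference is the
   cosolvent's effect on the folding free energy.
7. **SASA m-values.** Independently of the solvation route, an additive
   transfer model estimates `Δμ_tr = Σ_k (A_k/A_ref,k)·Δg_k` from
   backbone/side-chain solvent-accessible areas and per-group coefficients,
   and the m-value as the U−N difference at 1 mol/L.

## The ideal reference

The ideal minimum-distance distribution has no closed form for irregular
shapes, so it is sampled: `oversample × n_molecules` placements per frame,
each drawing a molecule conformation uniformly from the frame's real
molecules, a uniform random rotation (uniform unit quaternion) and a uniform
position of the first atom in the box. The reference is regenerated per
frame so box fluctuations are respected. The oversampling factor (default
10) only controls reference noise; a convergence property in the test suite
checks that doubling it moves the MDDF by less than the real-count sampling
error.

**Normalization.** The raw placement histogram estimates the probability
that a uniformly placed molecule falls at minimum distance r, i.e. the
minimum-distance *shell volume* as a fraction of the box. Reference counts
are obtained by multiplying this volume profile by the bulk density:
`n_s*(r) = ρ_s · V_box · P_ideal(r)`. An alternative — scaling the ideal
histogram to the same total molecule count as the real one — agrees in the
bulk for weak perturbations but biases the finite-volume KBI by a factor
(1 − V_min(R)/V_box), which is far from negligible in desk-scale boxes where
the cutoff sweeps a significant volume fraction. The bulk-referenced form
keeps `G(R)` equal to the true excess volume independently of box size; the
hard-sphere benchmark (below) is sensitive to exactly this choice.

**Bulk density estimator.** ρ_s is estimated from the molecules with
minimum distance beyond `d_bulk` (default 10 Å), divided by the matching
ideal volume fraction; this excludes the perturbed solvation region, which
the total N/V estimator would fold in. When the bulk region is empty the
code falls back to N/V with a warning. A `density_mode="total"` switch
selects N/V directly.

## Uncertainties

Statistical errors come from block averaging over frames (default 5
contiguous blocks; the statistical tests in the suite use 10 for a
better-conditioned variance estimate). Each block re-estimates its own bulk
density, because at large R the density uncertainty — not counting noise —
dominates the KBI error; block G values therefore carry both sources, and
Γ errors propagate through the block difference `ρ_c(G_pc − G_pw)`.
The plateau is the mean of G(R) over the final `plateau_window` Å (default
5) of the grid, with a flatness diagnostic (max−min over the window)
reported next to the block SE.

## Transfer-free-energy integration

Γ(m) is interpolated piecewise-linearly through the supplied concentration
series with the anchor Γ(0) = 0, which is physically forced
(Γ = ρ_c[G_pc − G_pw] vanishes with ρ_c) and removes the 1/m singularity of
the integrand. At m = 0 the integrand limit is −R·T·(M_p/M_c)·Γ′(0), with
Γ′(0) estimated from the parabola through the origin and the first two
series nodes (exact for linear and quadratic Γ). Integration is trapezoidal
on a refined grid (default 1000 nodes plus the series nodes). The printed
integrand convention carries the M_p/M_c mass ratio; because its
dimensional role differs between published formulations,
`include_mass_ratio=False` selects the molal variant without it. Activity
coefficients enter as a tabulated (m, ln γ) curve with central-difference
derivatives; the ideal model (γ ≡ 1) is the default, and no experimental
activity table is bundled.

## Synthetic configurations and ground truth

The generator is the package's stand-in for molecular-dynamics solvent
ensembles. It plants a target profile g_s(r) per species by rejection
sampling **on the minimum-distance coordinate itself**: proposals are
uniform rigid-body placements, accepted with probability g(r_min)/g_max, and
the proposal count is Poisson(ρ_s·V·g_max) so that the accepted set is a
Poisson process with intensity ρ_s·g_s(r) — far-field density exactly ρ_s,
no calibration constants. Because generator and estimator use the same
coordinate, every pipeline stage has a recoverable analytic ground truth:
`G_s = ∫(g_s−1)dV` over minimum-distance shells (evaluated by Monte-Carlo
quadrature against a large ideal sample, reported with its own error) and
`Γ_true = ρ_c(G_c − G_w)`.

Default study conditions are a dilute-osmolyte regime: cosolvent 0.5 mol/L
and water at 5.55 mol/L — liquid water scaled down tenfold so frames stay at
desk scale; the scaling is deliberate and flagged here because it enlarges
per-frame noise but leaves every expectation unchanged. What the generator
does **not** emulate: real water structure (no H-bond network, no
solvent–solvent correlations), force-field energetics, or conformational
coupling between solute and solvent. Passing tests therefore demonstrate
estimator correctness — unbiased recovery of planted structure — not the
physics of any particular solution.

Statistical test sizing: the analytic benchmarks run at 150–200 frames in
boxes of 24–30 Å with cutoffs of 8–12 Å, which puts 3-SE bands comfortably
inside the planted signals; Γ-recovery uses 20 replicas × 20 frames per
planted value. Bins for the flat-profile checks are 0.5 Å wide so that the
per-bin 3-SE criterion is tested over ~20 rather than hundreds of bins,
keeping the family-wise false-alarm probability at the percent level.
Negative planted Γ is realised as water accumulation rather than cosolvent
depletion: at ρ_c = 0.5 mol/L a depletion of two molecules would need an
exclusion shell beyond 11 Å, while the equivalent water bump stays inside
the analysis cutoff; the estimator is exercised identically either way.

## SASA

Shrake–Rupley with a deterministic golden-section-spiral point set (no RNG;
default 960 points, probe 1.4 Å), Bondi-style van der Waals radii shipped as
an overridable data file. Accuracy: exact for isolated spheres by
construction; two-sphere overlaps agree with the spherical-cap closed form
to <1% at 4000 points; rigid-body motion changes areas by <0.5% (the
lattice-orientation artifact bound). Backbone atoms are identified by name
(`N, CA, C, O, H, HA, HA2, HA3, HN, OXT` by default — glycine HA2/HA3 are
backbone); everything else is side chain. m-value coefficient tables are
user data with provenance strings; the shipped table is synthetic (for tests
and demonstrations) and the repository deliberately does not transcribe any
published coefficient set.

## Ensemble metrics

Q counts a contact as formed when the Cα–Cα distance does not exceed its
native value by more than the tolerance (default 20%) — the upper-bound
reading; contacts are inputs (pair list + native distance), with a helper to
derive native distances from a native structure. Superposition uses the
Kabsch algorithm (proper rotations only) via scipy's solver, with the
residual recomputed explicitly after rotation because the solver's reported
deviation loses half its digits to cancellation near zero. Representative
selection aligns all members to member 0, averages coordinates, and returns
the member with minimum RMSD to that mean in a single pass (no iterative
mean refinement); ties go to the lowest index. Population free energies are
`−R·T·ln(p_a/p_b)` with R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹.

## Numerical conventions and edge cases

- Units: Å, kcal/mol, K, g/mol; KBIs also reported in L/mol
  (1 Å³/molecule = 6.02214076×10⁻⁴ L/mol).
- Histogram bins are half-open `[i·w, (i+1)·w)`; a distance exactly at the
  cutoff is excluded. Bins with zero ideal counts (inside excluded volume)
  report MDDF = 0 with an explicit `defined` mask.
- Minimum-distance ties break to the lowest (solute-atom, solvent-atom)
  index pair. The distance kernel is an exact vectorised all-pairs
  computation, bitwise-identical to the brute-force double loop.
- Solutes larger than half the box in any dimension trigger a warning
  (minimum image ambiguous), not an error; cutoffs beyond half the smallest
  box length likewise warn.
- Orthorhombic boxes only; triclinic input raises an unsupported-feature
  error. Solvent molecules are fixed contiguous atom blocks; no bond
  perception.
- Multi-model PDB files must be read through `read_pdb_frames`; insertion
  codes and non-fixed-decimal coordinate fields are rejected with the line
  number.

## Known limitations

- The bulk-density estimator needs a genuine bulk region; highly
  concentrated solutes in small boxes fall back to N/V and inherit its bias.
- Γ at a single R is reported without the long-wavelength finite-size
  corrections used for closed-system KBIs; the plateau-window mean plus
  flatness diagnostic is the intended guard.
- The ideal reference shares conformations with the analysed frames, so
  strongly coupled intramolecular solvent distortions would bias both
  histograms equally rather than cancel exactly.
- SASA derivatives and power-diagram (analytic) areas are out of scope, as
  are DSSP-style secondary structure, WHAM analyses and 2D embeddings of
  folding landscapes.
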