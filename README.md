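# solvkb

Solvation structure and thermodynamics of solutes of arbitrary shape in
two-component solvents, from particle configurations.

`solvkb` is aimed at people studying how osmolytes (urea, TMAO, ...) shift
protein conformational equilibria. From frames of a solute in a
water + cosolvent box it computes **minimum-distance distribution functions**
(MDDFs), **finite-volume Kirkwood–Buff integrals** (KBIs), **preferential
interaction parameters** Γ, **Wyman-linkage** shifts ΔΓ between
conformational states, and **transfer free energies** by thermodynamic
integration. A second, structure-only route estimates **m-values** from
Shrake–Rupley solvent-accessible surface areas and an additive transfer
model, and a small ensemble toolkit covers fractions of native contacts Q,
Kabsch RMSD, representative-structure selection and Boltzmann population
free energies.

## The quantities

With `s ∈ {w, c}` (water, cosolvent), `p` the solute and r the *minimum*
distance between any solvent-molecule atom and any solute atom:

```
MDDF(r)  = n_s(r) / n_s*(r)                      ideal reference sampled numerically
G_ps(R)  = (1/ρ_s) [N_ps(R) − N_ps*(R)]          finite-volume Kirkwood–Buff integral
Γ_pc     = ρ_c [G_pc(R) − G_pw(R)]               preferential interaction parameter
ΔΓ_pc    = Γ_pc^U − Γ_pc^N = ∂lnK/∂ln a_c        Wyman linkage (ΔΓ > 0 favors U)
Δμ_p,tr(m) = ∫₀^m −Γ_pc R T (M_p/M_c) (1/m_c + ∂lnγ_c/∂m_c) dm_c
m-value  = Δμ_tr^U − Δμ_tr^N with Δμ_tr = Σ_k (A_k/A_ref,k) Δg_k   (SASA route)
```

Because the reaction coordinate is the minimum distance, everything is well
defined for folded and for highly extended conformations alike. A built-in
synthetic-configuration generator plants arbitrary bounded profiles g(r) by
rejection sampling on that same coordinate, so every stage of the pipeline
can be validated against analytic ground truth (`G_true = ∫(g−1)dV`,
`Γ_true = ρ_c(G_c − G_w)`).

## A worked example

```python
import numpy as np
from solvkb import accumulate_mddf, kbi_profile
from solvkb.synthetic import GeneratorSpec, HardCore, SpeciesSpec, generate
from solvkb.units import mol_per_L_to_per_A3

# 200 frames of an ideal fluid around a 3 Å hard-sphere solute
spec = GeneratorSpec(
    species=(SpeciesSpec("w", mol_per_L_to_per_A3(33.3), profile=HardCore(3.0)),),
    box=(30.0, 30.0, 30.0), n_frames=200, seed=6,
)
frames, truth = generate(spec)
result = accumulate_mddf(frames, "w", bin_width=0.1, cutoff=8.0,
                         oversample=40, seed=1, d_bulk=10.0)
profile = kbi_profile(result, n_blocks=10)
print(f"plateau G = {profile.plateau:.3f} ± {profile.plateau_se:.3f} Å³")
print(f"analytic  = {-(4/3)*np.pi*27:.3f} Å³")
```

prints (exact numbers vary with the seed):

```
plateau G = -114.524 ± 8.474 Å³
analytic  = -113.097 Å³
```

The plateau of the distance-resolved KBI recovers the solute's excluded
volume −(4/3)πa³ within its block-averaged error — the analytic benchmark
for the whole minimum-distance → KBI chain. The `examples/` directory holds
one short script per capability (MDDF normalization, hard-sphere KBI,
Γ and Wyman linkage on a two-state ensemble, transfer free energies, SASA
m-values, ensemble metrics), each printing its numbers with a line on what
they mean.

## Command line

The same stages are available as file-mediated subcommands for shell use:

```sh
solvkb synth --out-prefix demo --box 30 --n-frames 50 --seed 1 --bump-amplitude 5
solvkb mddf --frames demo.xyz --species c --out mddf_c.csv --seed 1
solvkb kbi  --mddf-table mddf_c.csv --out kbi_c.csv
solvkb gamma --kbi-c kbi_c.csv --kbi-w kbi_w.csv --out gamma.csv
solvkb transfer --gamma N=gamma_N.csv --gamma U=gamma_U.csv \
        --outdir transfer/ --m-p 9000 --m-c 60.06
```

plus `wyman`, `sasa`, `mvalue`, `qnative`, `represent` and `solvation`
(a full frames → Γ run from a YAML config, writing a manifest with content
hashes so reruns are verifiable).

## Layout

```
src/solvkb/      io, mindist, mddf, kbi, sasa, ensemble, synthetic, pipeline, cli
examples/        one narrative script per capability
tests/           unit, property and end-to-end scientific checks
docs/methods.md  models, estimators, conventions, limitations
```
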