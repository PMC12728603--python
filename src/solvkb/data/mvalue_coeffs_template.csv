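# cosolvent = <name, e.g. urea or TMAO>
# provenance = <citation for the experimental group transfer free energies>
# dg_cal_per_mol: group transfer free energy (cal/mol) at 1 mol/L cosolvent
# a_ref_A2: reference solvent-accessible area of the group (Å²)
# The 'backbone' group is mandatory; side-chain groups use 3-letter residue names.
group,dg_cal_per_mol,a_ref_A2
backbone,,
ALA,,
ARG,,
ASN,,
ASP,,
CYS,,
GLN,,
GLU,,
GLY,,
HIS,,
ILE,,
LEU,,
LYS,,
MET,,
PHE,,
PRO,,
SER,,
THR,,
TRP,,
TYR,,
VAL,,
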