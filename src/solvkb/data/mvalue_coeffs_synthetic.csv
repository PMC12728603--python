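# cosolvent = synthetic-example
# provenance = synthetic values for testing and demonstration only; NOT experimental group transfer free energies
group,dg_cal_per_mol,a_ref_A2
backbone,-40.0,40.0
ALA,10.0,70.0
ARG,-30.0,200.0
ASN,-25.0,125.0
ASP,-20.0,120.0
CYS,5.0,100.0
GLN,-28.0,150.0
GLU,-22.0,145.0
GLY,0.0,45.0
HIS,-15.0,160.0
ILE,25.0,155.0
LEU,22.0,160.0
LYS,-18.0,185.0
MET,12.0,165.0
PHE,18.0,190.0
PRO,8.0,120.0
SER,-10.0,95.0
THR,-8.0,115.0
TRP,15.0,225.0
TYR,5.0,200.0
VAL,20.0,135.0
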