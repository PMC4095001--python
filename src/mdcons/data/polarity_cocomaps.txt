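# Residue polarity dialect (COCOMAPS-style).
# Two columns: 3-letter residue name, class (hydrophobic | hydrophilic).
ALA hydrophobic
VAL hydrophobic
LEU hydrophobic
ILE hydrophobic
MET hydrophobic
PHE hydrophobic
PRO hydrophobic
TRP hydrophobic
GLY hydrophobic
SER hydrophilic
THR hydrophilic
CYS hydrophilic
TYR hydrophilic
ASN hydrophilic
GLN hydrophilic
ASP hydrophilic
GLU hydrophilic
LYS hydrophilic
ARG hydrophilic
HIS hydrophilic
# selenomethionine behaves as methionine
MSE hydrophobic
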