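residue,hydropathy,residue_mass,charge_ph7.4,aromatic,aliphatic,polar,positive,negative
A,1.8,71.08,0,0,1,0,0,0
C,2.5,103.14,0,0,0,0,0,0
D,-3.5,115.09,-1,0,0,0,0,1
E,-3.5,129.12,-1,0,0,0,0,1
F,2.8,147.18,0,1,0,0,0,0
G,-0.4,57.05,0,0,0,0,0,0
H,-3.2,137.14,0,1,0,0,1,0
I,4.5,113.16,0,0,1,0,0,0
K,-3.9,128.17,1,0,0,0,1,0
L,3.8,113.16,0,0,1,0,0,0
M,1.9,131.19,0,0,0,0,0,0
N,-3.5,114.10,0,0,0,1,0,0
P,-1.6,97.12,0,0,0,0,0,0
Q,-3.5,128.13,0,0,0,1,0,0
R,-4.5,156.19,1,0,0,0,1,0
S,-0.8,87.08,0,0,0,1,0,0
T,-0.7,101.10,0,0,0,1,0,0
V,4.2,99.13,0,0,1,0,0,0
W,-0.9,186.21,0,1,0,0,0,0
Y,-1.3,163.18,0,1,0,1,0,0
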