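name,row,col,midline
FP1,0,3,0
FPZ,0,4,1
FP2,0,5,0
AF3,1,3,0
AF4,1,5,0
F7,2,0,0
F5,2,1,0
F3,2,2,0
F1,2,3,0
FZ,2,4,1
F2,2,5,0
F4,2,6,0
F6,2,7,0
F8,2,8,0
FT7,3,0,0
FC5,3,1,0
FC3,3,2,0
FC1,3,3,0
FCZ,3,4,1
FC2,3,5,0
FC4,3,6,0
FC6,3,7,0
FT8,3,8,0
T7,4,0,0
C5,4,1,0
C3,4,2,0
C1,4,3,0
CZ,4,4,1
C2,4,5,0
C4,4,6,0
C6,4,7,0
T8,4,8,0
TP7,5,0,0
CP5,5,1,0
CP3,5,2,0
CP1,5,3,0
CPZ,5,4,1
CP2,5,5,0
CP4,5,6,0
CP6,5,7,0
TP8,5,8,0
P7,6,0,0
P5,6,1,0
P3,6,2,0
P1,6,3,0
PZ,6,4,1
P2,6,5,0
P4,6,6,0
P6,6,7,0
P8,6,8,0
PO7,7,1,0
PO5,7,2,0
PO3,7,3,0
POZ,7,4,1
PO4,7,5,0
PO6,7,6,0
PO8,7,7,0
CB1,8,2,0
O1,8,3,0
OZ,8,4,1
O2,8,5,0
CB2,8,6,0
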