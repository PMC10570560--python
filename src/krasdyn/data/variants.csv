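variant,position,hotspot,gdp_group,gtp_group
WT,,0,6,2
K5E,5,0,1,2
K5N,5,0,6,6
G12A,12,1,6,4
G12C,12,1,2,3
G12D,12,1,4,3
G12F,12,1,6,3
G12R,12,1,1,1
G12S,12,1,5,6
G12V,12,1,6,4
G13A,13,1,2,2
G13C,13,1,2,1
G13D,13,1,6,1
G13I,13,1,3,3
G13R,13,1,2,2
G13S,13,1,1,3
G13V,13,1,6,4
V14I,14,0,2,2
G15V,15,0,4,2
S17G,17,0,5,2
S17N,17,0,4,2
A18D,18,0,4,5
L19F,19,0,3,4
Q22E,22,0,3,2
Q22K,22,0,1,4
Q22L,22,0,1,2
Q22R,22,0,5,3
L23I,23,0,1,3
L23R,23,0,6,3
Q25H,25,0,6,5
N26I,26,0,1,1
N26S,26,0,1,6
N26Y,26,0,4,4
H27L,27,0,3,2
H27Y,27,0,5,2
F28L,28,0,5,5
F28S,28,0,2,3
D30E,30,0,6,3
E31Q,31,0,4,3
D33E,33,0,6,1
P34L,34,0,2,5
P34Q,34,0,5,2
P34R,34,0,2,3
P34S,34,0,1,4
T35A,35,0,1,4
T35I,35,0,4,1
I36L,36,0,1,2
I36M,36,0,6,3
D38N,38,0,5,1
L52F,52,0,4,2
A59T,59,0,6,2
G60A,60,0,5,4
G60R,60,0,1,4
G60S,60,0,2,4
G60V,60,0,4,4
Q61E,61,1,6,3
Q61H,61,1,1,3
Q61K,61,1,3,3
Q61L,61,1,5,1
Q61P,61,1,1,3
Q61R,61,1,5,2
E62D,62,0,3,3
E62G,62,0,1,2
E63K,63,0,1,1
S65I,65,0,1,4
R68M,68,0,1,2
R68S,68,0,2,6
Q70P,70,0,3,1
Y71C,71,0,4,6
Y71D,71,0,5,4
Y71H,71,0,4,4
M72I,72,0,1,4
M72L,72,0,4,1
T74A,74,0,1,3
T74P,74,0,3,6
H95N,95,0,1,6
K117E,117,0,2,1
K117N,117,0,1,6
K117R,117,0,2,3
A130V,130,0,4,1
R135T,135,0,6,4
I142T,142,0,4,3
A146T,146,0,4,1
A146V,146,0,1,5
L159S,159,0,6,3
V160M,160,0,6,1
R164Q,164,0,1,3
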