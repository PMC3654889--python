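# Seven amino-acid classes grouped by the dipoles and side-chain volumes:
# 1 {A,G,V}  2 {C}  3 {D,E}  4 {F,I,L,P}  5 {H,N,Q,W}  6 {K,R}  7 {M,S,T,Y}
aa	group
A	1
G	1
V	1
C	2
D	3
E	3
F	4
I	4
L	4
P	4
H	5
N	5
Q	5
W	5
K	6
R	6
M	7
S	7
T	7
Y	7
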