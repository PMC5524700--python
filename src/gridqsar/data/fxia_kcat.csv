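code,mutation,substrate,kcat,activity_class
A,A,S-2288,64.8,moderate
B,D,S-2288,4.2,low
C,E,S-2288,71.2,moderate
D,K,S-2288,30.0,low
E,V,S-2288,10.0,low
F,G,S-2288,110.2,high
G,A,S-2366,117.0,high
H,D,S-2366,40.8,low
I,E,S-2366,98.0,high
J,K,S-2366,114.2,high
K,V,S-2366,26.7,low
L,G,S-2366,145.0,very_high
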