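symbol,weight
H,1.008
B,10.81
C,12.011
N,14.007
O,15.999
Na,22.990
Mg,24.305
Al,26.982
Si,28.085
P,30.974
S,32.06
Cl,35.45
K,39.098
Ca,40.078
Mn,54.938
Fe,55.845
Co,58.933
Ni,58.693
Cu,63.546
Zn,65.38
As,74.922
Se,78.971
Mo,95.95
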