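symbol,atomic_number,atomic_weight,valence_electrons,pauling_electronegativity,polarizability,covalent_radius
H,1,1.008,1,2.20,0.6668,0.32
B,5,10.811,3,2.04,3.03,0.84
C,6,12.011,4,2.55,1.76,0.77
N,7,14.007,5,3.04,1.10,0.71
O,8,15.999,6,3.44,0.802,0.66
F,9,18.998,7,3.98,0.557,0.64
Si,14,28.086,4,1.90,5.38,1.11
P,15,30.974,5,2.19,3.63,1.07
S,16,32.06,6,2.58,2.90,1.05
Cl,17,35.453,7,3.16,2.18,0.99
Se,34,78.971,6,2.55,3.77,1.20
Br,35,79.904,7,2.96,3.05,1.14
I,53,126.904,7,2.66,5.35,1.33
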