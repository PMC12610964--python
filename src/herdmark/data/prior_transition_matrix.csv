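state,T,H,THI,F,M,L,S,RS,RL
T,0.141,0.114,0.111,0.101,0.101,0.143,0.094,0.107,0.084
H,0.145,0.122,0.119,0.106,0.088,0.122,0.1,0.114,0.081
THI,0.144,0.122,0.119,0.106,0.088,0.121,0.1,0.114,0.081
F,0.124,0.103,0.101,0.104,0.116,0.159,0.094,0.1,0.095
M,0.074,0.051,0.049,0.069,0.207,0.292,0.068,0.058,0.127
L,0.074,0.05,0.048,0.067,0.206,0.304,0.066,0.056,0.125
S,0.12,0.1,0.098,0.098,0.118,0.163,0.099,0.1,0.098
RS,0.135,0.113,0.111,0.102,0.099,0.138,0.099,0.111,0.088
RL,0.086,0.065,0.064,0.079,0.177,0.248,0.079,0.071,0.127
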