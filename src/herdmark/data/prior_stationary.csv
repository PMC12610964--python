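state,pi,cumulative
T,0.108,0.108
H,0.085,0.194
THI,0.083,0.277
F,0.088,0.366
M,0.147,0.513
L,0.209,0.722
S,0.085,0.807
RS,0.086,0.894
RL,0.106,1.0
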