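cow,n_iterations,aae,aes,rmse
1,3000,0.046923,0.003663,0.060527
1,4000,0.029635,0.002304,0.048
1,5000,0.021482,0.000958,0.030953
2,3000,0.047203,0.003804,0.061676
2,4000,0.035593,0.002005,0.044773
2,5000,0.028498,0.002093,0.045748
3,3000,0.045708,0.003886,0.062339
3,4000,0.038125,0.002914,0.053983
3,5000,0.028295,0.00155,0.039373
4,3000,0.038484,0.002362,0.048605
4,4000,0.038125,0.002137,0.046233
4,5000,0.025685,0.001056,0.032495
5,3000,0.041612,0.002782,0.05274
5,4000,0.035671,0.00201,0.044836
5,5000,0.027747,0.001993,0.044639
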