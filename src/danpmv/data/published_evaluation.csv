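code,kind,dimension,weight,global_weight,expert_performance,expert_gap,user_performance,user_gap
D1,dimension,D1,0.221,,5.246,0.475,6.081,0.392
C11,criterion,D1,0.257,0.057,5.100,0.490,6.159,0.384
C12,criterion,D1,0.241,0.053,5.600,0.440,6.385,0.361
C13,criterion,D1,0.252,0.056,5.300,0.470,5.889,0.411
C14,criterion,D1,0.250,0.055,5.000,0.500,5.901,0.410
D2,dimension,D2,0.180,,4.746,0.525,6.200,0.380
C21,criterion,D2,0.240,0.043,4.600,0.540,6.105,0.389
C22,criterion,D2,0.166,0.030,5.300,0.470,6.293,0.371
C23,criterion,D2,0.217,0.039,5.200,0.480,6.436,0.356
C24,criterion,D2,0.207,0.037,4.200,0.580,6.124,0.388
C25,criterion,D2,0.171,0.031,4.500,0.550,6.032,0.397
D3,dimension,D3,0.183,,4.607,0.539,6.129,0.387
C31,criterion,D3,0.316,0.058,4.300,0.570,6.064,0.394
C32,criterion,D3,0.351,0.064,4.700,0.530,6.175,0.382
C33,criterion,D3,0.332,0.061,4.800,0.520,6.143,0.386
D4,dimension,D4,0.239,,5.448,0.455,6.256,0.374
C41,criterion,D4,0.251,0.060,5.500,0.450,6.258,0.374
C42,criterion,D4,0.254,0.061,5.400,0.460,6.258,0.374
C43,criterion,D4,0.262,0.062,5.400,0.460,6.315,0.368
C44,criterion,D4,0.234,0.056,5.500,0.450,6.185,0.382
D5,dimension,D5,0.177,,4.648,0.535,6.323,0.368
C51,criterion,D5,0.253,0.045,5.400,0.460,6.309,0.369
C52,criterion,D5,0.245,0.043,4.600,0.540,6.299,0.370
C53,criterion,D5,0.242,0.043,4.500,0.550,6.401,0.360
C54,criterion,D5,0.260,0.046,4.100,0.590,6.287,0.371
TOTAL,total,,,,4.982,0.502,6.196,0.380
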