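subject,norm_yaman_during,norm_yaman_after,norm_pd_during,norm_pd_after,mean_yaman_during,mean_yaman_after,mean_pd_during,mean_pd_after
1,0.48,0.40,0.59,1.66,0.74,0.62,0.60,0.89
2,0.55,0.65,0.71,0.53,0.52,0.79,0.71,0.60
3,0.60,0.49,1.31,0.48,0.62,0.50,0.75,0.53
4,0.78,0.99,0.74,0.62,0.78,0.84,0.54,0.56
5,0.54,0.89,0.53,0.62,0.57,0.60,0.62,0.57
6,0.95,0.83,0.39,1.00,0.62,0.66,0.58,0.76
7,0.76,0.70,0.53,0.52,0.79,0.74,0.80,0.62
8,0.44,0.65,0.54,0.86,0.51,0.95,0.57,0.88
9,0.42,0.80,0.79,0.60,0.48,0.63,0.75,0.64
10,0.72,0.43,0.45,0.71,0.67,0.74,0.84,0.62
11,0.77,0.66,0.59,0.95,0.80,0.63,0.66,0.67
12,0.71,0.63,1.28,0.64,0.73,0.56,0.90,0.77
13,0.83,0.85,0.62,1.42,0.72,0.83,0.57,0.86
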