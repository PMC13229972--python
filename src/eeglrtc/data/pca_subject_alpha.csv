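subject,norm_yaman_during,norm_yaman_after,norm_pd_during,norm_pd_after,mean_yaman_during,mean_yaman_after,mean_pd_during,mean_pd_after
1,0.48,0.41,0.55,1.62,0.65,0.60,0.64,0.67
2,0.56,0.67,0.73,0.54,0.52,0.70,0.57,0.57
3,0.59,0.50,1.33,0.49,0.59,0.61,0.70,0.66
4,0.74,1.04,0.70,0.62,0.71,0.68,0.54,0.61
5,0.53,0.92,0.55,0.57,0.59,0.62,0.59,0.57
6,0.97,0.84,0.41,0.96,0.55,0.58,0.56,0.71
7,0.80,0.73,0.62,0.48,0.70,0.72,0.68,0.64
8,0.44,0.67,0.57,0.83,0.53,0.71,0.59,0.77
9,0.43,0.84,0.80,0.59,0.52,0.70,0.67,0.61
10,0.62,0.49,0.49,0.70,0.68,0.67,0.70,0.63
11,0.75,0.64,0.53,0.95,0.75,0.66,0.61,0.66
12,0.69,0.55,1.32,0.65,0.69,0.58,0.74,0.73
13,0.81,0.87,0.60,1.43,0.61,0.77,0.56,0.80
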