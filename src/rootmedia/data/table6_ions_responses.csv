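code,no3_mm,nh4_mm,k_mm,ca_mm,cl_mm,rn_mean,rn_se,rl_mean,rl_se,rpct_mean,rpct_se,fw_mean,fw_se,dw_mean,dw_se
1,44.12,20.62,18.79,2.35,0.0,8.17,0.31,7.08,0.05,0.43,0.02,0.43,0.01,0.07,0.004
2,41.78,20.62,18.79,1.18,0.0,7.33,0.42,7.42,0.08,0.41,0.01,0.48,0.01,0.09,0.001
3,38.97,15.47,18.79,2.35,0.0,7.16,0.31,7.03,0.08,0.41,0.02,0.4,0.01,0.06,0.006
4,36.63,15.47,18.79,1.18,0.0,6.33,0.33,7.55,0.04,0.36,0.01,0.46,0.01,0.09,0.006
5,33.81,10.31,18.79,2.35,0.0,5.67,0.33,7.11,0.04,0.36,0.02,0.36,0.005,0.04,0.004
6,31.47,10.31,18.79,1.18,0.0,5.5,0.34,7.45,0.04,0.37,0.01,0.42,0.007,0.07,0.004
7,39.42,20.62,14.09,2.35,0.0,10.16,0.31,6.75,0.06,0.71,0.01,0.51,0.005,0.1,0.003
8,37.08,20.62,14.09,1.18,0.0,10.16,0.6,7.0,0.04,0.69,0.01,0.56,0.007,0.13,0.004
9,34.27,15.47,14.09,2.35,0.0,10.0,0.58,6.8,0.04,0.65,0.01,0.58,0.006,0.15,0.008
10,31.93,15.47,14.09,1.18,0.0,8.33,0.31,7.2,0.05,0.61,0.01,0.51,0.01,0.1,0.006
11,29.11,10.31,14.09,2.35,0.0,8.16,0.31,7.02,0.02,0.52,0.02,0.47,0.008,0.08,0.004
12,26.77,10.31,14.09,1.18,0.0,7.5,0.43,7.33,0.05,0.51,0.01,0.53,0.006,0.12,0.005
13,34.73,20.62,9.4,2.35,0.0,15.0,0.36,6.82,0.05,0.97,0.01,0.69,0.009,0.18,0.013
14,32.39,20.62,9.4,1.18,0.0,13.33,0.49,6.5,0.04,0.95,0.01,0.74,0.006,0.23,0.008
15,29.58,15.47,9.4,2.35,0.0,11.0,0.36,6.98,0.03,0.9,0.01,0.67,0.004,0.17,0.01
16,27.24,15.47,9.4,1.18,0.0,9.33,0.33,6.63,0.05,0.85,0.01,0.63,0.006,0.15,0.009
17,24.42,10.31,9.4,2.35,0.0,9.0,0.26,6.71,0.02,0.8,0.01,0.58,0.008,0.13,0.007
18,22.08,10.31,9.4,1.18,0.0,8.0,0.26,6.41,0.03,0.75,0.01,0.53,0.007,0.11,0.006
19,39.41,20.62,18.79,3.0,3.0,5.16,0.31,7.61,0.05,0.34,0.01,0.34,0.027,0.05,0.007
20,39.41,20.62,18.79,1.5,1.5,6.67,0.33,7.2,0.06,0.38,0.01,0.37,0.025,0.07,0.008
21,34.26,15.47,18.79,3.0,3.0,6.17,0.16,7.37,0.04,0.32,0.01,0.39,0.008,0.06,0.005
22,34.26,15.47,18.79,1.5,1.5,5.5,0.22,7.48,0.03,0.36,0.008,0.34,0.016,0.05,0.008
23,29.1,10.31,18.79,3.0,3.0,5.17,0.17,7.52,0.03,0.32,0.01,0.35,0.013,0.06,0.008
24,29.1,10.31,18.79,1.5,1.5,4.67,0.42,7.75,0.07,0.28,0.011,0.33,0.013,0.04,0.004
25,34.71,20.62,14.09,3.0,3.0,9.67,0.21,6.8,0.06,0.59,0.015,0.54,0.014,0.12,0.009
26,34.71,20.62,14.09,1.5,1.5,10.33,0.33,6.63,0.09,0.62,0.011,0.59,0.012,0.15,0.011
27,29.56,15.47,14.09,3.0,3.0,7.5,0.22,7.1,0.06,0.52,0.01,0.5,0.013,0.1,0.004
28,29.56,15.47,14.09,1.5,1.5,7.67,0.21,7.0,0.08,0.53,0.011,0.56,0.014,0.13,0.008
29,24.4,10.31,14.09,3.0,3.0,6.83,0.17,7.17,0.11,0.46,0.02,0.44,0.018,0.08,0.006
30,24.4,10.31,14.09,1.5,1.5,7.33,0.21,6.98,0.1,0.48,0.01,0.48,0.011,0.1,0.007
31,30.02,20.62,9.4,3.0,3.0,10.83,0.31,6.48,0.05,0.83,0.016,0.61,0.008,0.17,0.005
32,30.02,20.62,9.4,1.5,1.5,12.17,0.48,6.28,0.04,0.87,0.011,0.67,0.009,0.22,0.009
33,24.87,15.47,9.4,3.0,3.0,10.0,0.36,6.7,0.08,0.77,0.011,0.55,0.007,0.12,0.004
34,24.87,15.47,9.4,1.5,1.5,9.83,0.17,6.55,0.07,0.82,0.01,0.59,0.009,0.15,0.009
35,19.71,10.31,9.4,3.0,3.0,8.5,0.22,7.0,0.08,0.67,0.021,0.48,0.008,0.1,0.004
36,19.71,10.31,9.4,1.5,1.5,9.0,0.36,6.85,0.09,0.74,0.015,0.54,0.014,0.13,0.007
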