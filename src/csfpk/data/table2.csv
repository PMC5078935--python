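patient,crcl,cmin_1000,cmax_1000,ctrough_1000,cafter4h_1000,cmin_2000,cmax_2000,ctrough_2000,cafter4h_2000
1,60.7,3.80,NA,2.00,NA,10.90,48.60,3.00,4.00
2,156.8,6.90,11.00,NA,NA,4.60,26.35,2.75,2.60
3,83.8,4.80,24.10,2.60,1.90,13.80,45.30,2.25,3.45
4,162.9,NA,NA,NA,NA,1.10,16.40,0.60,0.60
5,217.6,<0.5,5.80,NA,NA,2.90,19.40,0.31,0.53
6,124.5,NA,NA,NA,NA,0.86,19.20,0.76,0.86
7,120.1,NA,NA,NA,NA,<0.5,15.20,0.43,0.78
8,73.1,NA,NA,NA,NA,11.00,64.80,3.35,3.00
9,92.1,0.81,12.30,1.08,0.97,3.05,19.65,1.40,1.97
10,96.3,NA,NA,NA,NA,1.31,33.30,1.62,1.04
11,142.9,NA,12.82,NA,1.14,1.02,19.33,0.62,0.74
12,174.1,0.62,5.62,0.39,0.32,NA,NA,NA,NA
13,100.3,1.38,10.65,1.47,1.15,0.79,19.80,0.87,0.80
14,96.2,NA,NA,NA,NA,9.83,32.94,2.27,2.19
15,108.8,NA,NA,NA,NA,1.13,17.51,1.18,0.88
16,125.0,NA,NA,NA,NA,2.99,27.01,0.92,1.17
17,144.7,NA,NA,NA,NA,2.44,18.15,0.74,0.58
18,90.5,NA,20.10,NA,2.28,7.63,33.80,2.39,1.84
19,131.3,2.50,17.47,0.89,0.83,6.22,26.94,1.79,1.82
20,174.6,NA,NA,NA,NA,2.63,23.23,1.52,1.58
21,122.5,1.69,10.57,<0.2,0.25,3.65,16.74,0.31,0.44
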