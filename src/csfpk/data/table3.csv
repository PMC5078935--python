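patient,cl,v_c,t_half,auc24_serum,auc24_csf,csf_serum_ratio,t_half_cb,t_half_bc
1,7.63,6.45,0.59,768.63,85.53,0.11,3.30,4.62
2,17.88,14.45,0.56,327.09,53.00,0.16,17.33,9.90
3,8.62,14.95,1.20,428.94,48.59,0.11,4.62,3.47
4,20.38,5.05,0.17,300.14,19.37,0.06,13.86,17.33
5,22.87,14.95,0.45,237.60,8.93,0.04,17.33,2.57
6,14.89,5.05,0.24,401.45,18.63,0.05,34.66,69.31
7,23.37,14.95,0.44,258.79,15.02,0.06,34.66,5.78
8,7.88,5.05,0.44,760.20,79.10,0.10,8.66,9.90
9,17.13,14.95,0.60,280.81,26.56,0.09,23.10,17.33
10,11.88,13.75,0.80,489.44,27.25,0.06,69.31,34.66
11,20.63,12.75,0.43,287.15,15.59,0.05,34.66,17.33
12,29.87,9.95,0.23,112.95,10.56,0.09,11.55,9.90
13,15.07,5.05,0.23,234.65,22.10,0.09,23.10,69.31
14,9.63,14.95,1.08,569.59,48.90,0.09,13.86,5.78
15,14.88,5.05,0.24,413.23,25.62,0.06,34.66,69.31
16,17.13,14.95,0.60,337.21,30.99,0.09,23.10,17.33
17,14.98,5.08,0.24,415.22,17.31,0.04,34.66,69.31
18,10.63,5.05,0.33,563.84,42.95,0.08,5.78,8.66
19,13.12,14.95,0.79,394.45,33.99,0.09,34.66,13.86
20,17.13,14.95,0.60,350.22,33.71,0.10,23.10,17.33
21,18.88,14.15,0.52,242.60,7.44,0.03,17.33,1.73
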