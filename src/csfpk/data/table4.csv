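parameter,mean,median,sd
cl,16.045,15.025,5.575
v_c,10.949,13.736,4.491
k_cp,1.562,1.248,1.031
k_pc,1.686,1.898,1.206
k_cb,0.052,0.026,0.049
k_bc,0.092,0.054,0.097
v_csf,82.932,93.902,18.802
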