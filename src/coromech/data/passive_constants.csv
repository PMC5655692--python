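table,subject,C1,a1,a2,a3,a4,a5,a6,R2_T_theta_passive,R2_T_z_passive,R2_T_r_passive
wall,Heart 1,5.70,1.96,6.60,6.11,1.72,6.70,1.64,0.964,0.953,0.957
wall,Heart 2,3.64,3.02,9.60,5.70,1.19,8.20,1.61,0.974,0.968,0.968
wall,Heart 3,9.30,2.44,2.13,1.71,3.51,3.99,4.16,0.938,0.902,0.935
wall,Heart 4,4.72,4.81,3.30,8.63,10.30,5.02,2.81,0.921,0.932,0.937
wall,Heart 5,8.10,3.02,1.19,1.61,11.22,2.36,0.50,0.902,0.878,0.941
wall,Mean,6.29,3.05,4.56,4.75,5.59,5.25,2.15,0.940,0.927,0.948
wall,SD,2.35,1.08,3.48,3.04,4.81,2.28,1.39,0.03,0.03,0.01
IM,Heart 1,6.29,2.79,1.64,5.49,2.50,3.20,2.11,0.999,0.999,0.999
IM,Heart 2,4.58,3.51,2.29,4.1,4.22,2.72,2.93,0.992,0.993,0.992
IM,Heart 3,7.21,5.23,2.56,5.67,4.21,4.56,2.44,0.998,0.990,0.986
IM,Heart 4,2.38,4.45,3.28,3.26,3.84,3.52,1.26,0.950,0.953,0.946
IM,Heart 5,4.41,6.63,5.68,4.13,4.63,5.72,6.19,0.908,0.891,0.910
IM,Heart 6,5.92,7.16,5.21,3.02,5.99,6.26,4.99,0.923,0.928,0.922
IM,Mean,5.13,4.96,3.44,4.28,4.23,4.33,3.32,0.962,0.959,0.959
IM,SD,1.71,1.51,1.55,1.04,0.84,1.48,1.99,0.04,0.04,0.04
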