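table,subject,C2,b1,b2,b3,b_prime,R2_T_theta_active,R2_T_z_active,R2_T_r_active
wall,Heart 1,17.6,0.54,1.08,2.40,5.45,0.908,0.938,0.914
wall,Heart 2,12.3,0.25,0.41,1.02,9.43,0.912,0.936,0.951
wall,Heart 3,7.78,0.18,0.44,0.68,11.8,0.981,0.939,0.941
wall,Heart 4,11.1,0.79,1.21,3.72,4.06,0.920,0.899,0.902
wall,Heart 5,15.1,0.48,0.99,1.62,5.63,0.918,0.975,0.927
wall,Mean,12.8,0.45,0.83,1.89,7.28,0.928,0.937,0.927
wall,SD,3.76,0.24,0.37,1.21,3.22,0.03,0.03,0.02
IM,Heart 1,49.8,0.55,1.13,4.66,4.79,0.997,0.991,0.996
IM,Heart 2,47.5,0.43,0.92,1.60,6.28,0.995,0.997,0.996
IM,Heart 3,42.1,0.49,1.05,3.14,5.23,0.997,0.996,0.998
IM,Heart 4,40.3,0.64,1.32,7.37,3.96,0.955,0.989,0.942
IM,Heart 5,40.2,0.34,0.72,5.77,5.94,0.964,0.979,0.959
IM,Heart 6,45.2,0.58,1.22,3.20,4.86,0.966,0.982,0.962
IM,Mean,44.2,0.51,1.06,4.29,5.18,0.979,0.989,0.976
IM,SD,3.63,0.10,0.20,1.90,0.77,0.02,0.01,0.02
two_layer,IM,28.92,0.43,1.62,4.38,4.87,,,
fig4,wall,,0.35,0.47,1.89,,,,
fig4_2d,wall,,0.12,0.18,,,,,
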