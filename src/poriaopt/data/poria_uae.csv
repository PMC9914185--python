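run,x1_ethanol_pct,x2_time_min,x3_volume_ml,PA_mean,PA_sd,TA_mean,TA_sd,TAA_mean,TAA_sd,DA_mean,DA_sd,TPs_mean,TPs_sd,TPc_mean,TPc_sd,DPPH_SC_mean,DPPH_SC_sd,T_AOC_mean,T_AOC_sd
1,50,40,40,434.57,10.16,35.78,4.01,109.94,6.95,68.75,5.12,29.24,2.54,241.14,6.11,5.55,0.25,1.27,0.11
2,50,50,20,17.54,3.84,7.36,4.36,13.43,4.39,12.89,3.26,7.71,2.93,154.71,4.89,8.89,0.47,1.18,0.16
3,75,40,20,355.47,10.52,39.44,7.00,94.36,3.82,74.90,5.06,33.83,2.80,220.61,4.53,12.50,0.24,1.65,0.20
4,75,40,60,487.26,5.02,29.06,5.25,119.07,5.62,75.48,5.57,28.99,2.92,249.83,4.45,10.78,0.47,1.03,0.12
5,50,30,20,38.00,2.64,24.81,2.30,20.54,3.54,59.08,8.18,36.60,2.20,281.69,4.55,10.46,0.37,1.53,0.08
6,25,50,40,89.34,2.62,5.36,2.60,22.10,4.00,5.14,1.12,14.66,0.69,215.27,3.93,4.23,0.30,0.95,0.06
7,50,50,60,672.10,9.77,51.25,6.53,179.60,3.88,104.45,5.52,40.73,2.52,250.96,4.55,8.27,0.31,0.99,0.03
8,50,40,40,421.83,13.04,37.65,4.45,117.05,6.67,81.98,9.02,22.75,3.10,243.32,2.03,5.80,0.35,1.25,0.14
9,50,40,40,426.13,12.66,33.03,4.57,106.05,2.83,67.32,3.80,26.31,2.34,243.49,4.66,5.29,0.22,1.27,0.20
10,25,30,40,33.57,5.03,3.42,1.40,7.80,1.95,11.51,2.46,24.90,1.59,301.98,6.95,3.57,0.45,1.35,0.01
11,50,30,60,542.10,6.40,33.99,3.22,142.41,4.29,88.08,3.44,36.32,0.58,284.16,6.67,4.13,0.41,1.09,0.14
12,25,40,20,26.51,4.86,5.12,2.22,6.25,1.63,10.39,4.81,26.24,1.41,250.68,3.52,11.10,0.65,1.69,0.02
13,50,40,40,412.60,6.02,30.97,3.40,111.01,6.80,68.27,5.37,23.08,3.45,240.52,2.97,5.27,0.84,1.29,0.23
14,75,50,40,452.91,10.50,29.45,1.84,118.06,3.66,63.65,3.92,19.89,2.30,203.07,3.83,5.44,0.27,0.90,0.06
15,50,40,40,415.27,5.11,36.49,2.06,122.14,12.26,79.18,11.13,26.67,3.11,245.10,2.79,5.32,0.21,1.33,0.16
16,25,40,60,55.72,9.37,4.10,1.59,12.12,1.63,11.49,4.24,28.85,2.50,265.78,6.10,9.23,0.36,1.05,0.17
17,75,30,40,429.31,4.72,32.00,3.25,111.96,4.14,81.72,2.99,28.91,2.39,260.09,2.26,4.03,0.36,1.14,0.06
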