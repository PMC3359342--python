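# Station growth summaries: von Bertalanffy parameters with asymptotic 95% CI
# bounds (lo/hi), fit R^2, growth performance index phi_prime (2 dp), and MDG
# (mean of the 10 widest successive daily increments, um/d) +- standard error.
station_id,name,h_inf,h_inf_lo,h_inf_hi,k,k_lo,k_hi,t0,t0_lo,t0_hi,r2,phi_prime,mdg,mdg_se
1,Vigo,109.7,107.6,111.8,0.67,0.62,0.72,0.50,0.46,0.54,0.96,1.91,257.9,5.1
2,Ile de Re,101.1,98.4,103.8,0.68,0.61,0.75,0.47,0.41,0.53,0.95,1.84,217.7,2.1
3,Bay of Brest,103.6,101.3,105.9,0.83,0.76,0.90,0.56,0.52,0.60,0.97,1.95,241.0,1.6
4,Bay of Seine,108.4,104.7,112.0,0.87,0.76,0.97,0.58,0.53,0.63,0.95,2.01,260.9,1.3
5,Plymouth,108.4,102.9,113.8,0.61,0.52,0.71,0.48,0.40,0.56,0.96,1.86,223.1,2.4
6,Holyhead,143.6,136.3,150.9,0.26,0.23,0.29,0.41,0.32,0.49,0.97,1.73,261.3,2.1
7,Scarborough,137.0,126.8,147.2,0.25,0.21,0.29,0.40,0.31,0.50,0.95,1.67,273.3,5.6
8,Campbell Town,146.9,131.9,161.8,0.23,0.18,0.27,0.19,0.07,0.31,0.95,1.70,264.8,3.4
9,Austevoll,155.9,126.5,185.2,0.20,0.13,0.28,0.36,0.16,0.56,0.95,1.69,210.6,1.0
10,Bessaker,127.2,118.5,135.9,0.28,0.24,0.33,0.42,0.30,0.55,0.94,1.66,235.6,2.9
11,Bronnoysund,133.5,128.6,138.4,0.23,0.21,0.25,0.54,0.46,0.61,0.97,1.61,240.6,5.8
12,Traena,144.5,139.3,149.8,0.24,0.22,0.26,0.56,0.49,0.63,0.97,1.70,261.0,1.8
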