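index,hr_bpm,spo2_pct,ambient_c,body_c,speed_cm_s,alert
1,83.18,96.00,33.37,34.98,15.87,0
2,84.47,96.00,33.34,34.79,21.52,0
3,79.67,96.00,33.31,34.61,16.45,0
4,85.23,95.80,33.28,34.47,18.78,0
5,90.14,95.60,33.25,34.53,23.17,0
6,91.19,95.60,33.22,34.62,21.46,0
7,90.61,95.60,33.19,34.54,21.76,0
8,89.07,95.60,33.16,34.43,30.21,0
9,94.71,95.80,33.13,34.34,36.18,0
10,85.58,96.00,33.09,34.29,34.37,0
11,81.02,96.00,33.05,34.25,34.59,0
12,78.88,96.00,33.01,34.28,32.69,0
13,77.06,96.20,32.96,34.35,31.84,0
14,69.33,96.40,32.91,34.38,32.12,0
15,73.37,96.60,32.88,34.40,35.66,0
16,76.70,96.80,32.85,34.39,39.64,0
17,78.04,97.00,32.83,34.31,37.70,0
18,78.72,97.00,32.81,34.29,34.30,0
19,76.14,97.00,32.78,34.29,37.83,0
20,72.03,97.00,32.75,34.20,38.74,0
21,68.50,97.00,32.73,34.19,34.91,0
22,66.96,97.00,32.69,34.24,35.40,0
23,65.11,97.00,32.66,34.24,41.01,0
24,63.25,97.00,32.63,34.27,41.22,0
25,67.89,97.00,32.61,34.33,30.88,0
26,69.35,97.00,32.58,34.35,35.57,0
27,70.99,97.00,32.55,34.37,39.26,0
28,76.23,97.00,32.54,34.32,34.38,0
29,77.54,97.00,32.52,34.34,25.90,0
30,77.47,97.00,32.49,34.27,34.43,0
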