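index,hr_bpm,spo2_pct,ambient_c,body_c,speed_cm_s,alert
1,83.94,96.00,33.39,35.44,9.05,0
2,83.84,96.00,33.38,35.26,11.66,0
3,83.41,95.99,33.36,35.03,14.62,0
4,83.13,95.96,33.34,34.81,17.27,0
5,83.72,95.91,33.31,34.66,19.08,0
6,85.50,95.81,33.28,34.58,19.98,0
7,87.98,95.70,33.25,34.56,20.79,0
8,90.07,95.62,33.22,34.54,22.54,0
9,90.76,95.62,33.19,34.50,25.53,0
10,89.98,95.70,33.16,34.44,29.11,0
11,88.37,95.82,33.12,34.37,32.23,0
12,86.23,95.92,33.09,34.31,33.99,0
13,83.17,96.00,33.05,34.29,34.08,0
14,79.19,96.09,33.00,34.31,33.17,0
15,75.56,96.22,32.96,34.34,32.63,0
16,73.86,96.40,32.92,34.37,33.50,0
17,74.40,96.60,32.88,34.37,35.50,0
18,76.01,96.78,32.85,34.36,37.24,0
19,77.05,96.90,32.83,34.33,37.55,0
20,76.62,96.96,32.80,34.30,36.71,0
21,74.80,96.99,32.78,34.27,36.10,0
22,72.22,97.00,32.75,34.24,36.64,0
23,69.58,97.00,32.72,34.23,37.67,0
24,67.40,97.00,32.69,34.23,37.96,0
25,66.14,97.00,32.66,34.25,37.41,0
26,66.11,97.00,32.63,34.28,36.86,0
27,67.37,97.00,32.60,34.31,36.62,0
28,69.62,97.00,32.58,34.33,36.10,0
29,72.22,97.00,32.56,34.34,34.94,0
30,74.51,97.00,32.54,34.33,33.55,0
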