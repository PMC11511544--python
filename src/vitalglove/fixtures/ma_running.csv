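index,hr_bpm,spo2_pct,ambient_c,body_c,speed_cm_s,alert
1,93.73,97.00,32.67,36.11,85.24,0
2,100.55,97.00,32.67,36.00,109.11,0
3,100.91,97.00,32.66,35.95,115.30,0
4,98.20,96.80,32.66,35.90,125.85,0
5,87.74,96.60,32.65,35.88,161.78,0
6,82.96,95.80,32.64,35.89,142.95,0
7,82.58,95.00,32.63,35.84,138.77,0
8,95.10,94.80,32.61,35.73,149.30,0
9,98.93,94.80,32.59,35.63,175.24,0
10,114.06,94.80,32.57,35.50,139.38,0
11,131.34,95.40,32.55,35.42,128.18,0
12,139.85,96.00,32.54,35.42,142.16,0
13,140.43,96.00,32.52,35.40,169.74,0
14,150.99,96.00,32.49,35.41,151.10,0
15,146.32,96.00,32.47,35.41,193.05,1
16,143.56,96.00,32.46,35.35,195.91,1
17,142.03,96.00,32.43,35.28,198.32,0
18,144.72,96.00,32.41,35.31,173.86,0
19,146.79,96.00,32.39,35.26,180.63,0
20,151.40,96.00,32.37,35.19,145.75,0
21,149.60,96.00,32.36,35.19,169.60,0
22,146.50,96.00,32.33,35.10,151.50,1
23,139.87,96.00,32.31,35.04,181.89,1
24,123.85,96.00,32.29,35.06,158.15,0
25,108.94,96.00,32.27,35.21,178.98,0
26,96.00,96.00,32.25,35.31,145.44,0
27,84.56,96.00,32.25,35.47,143.66,0
28,81.52,96.00,32.24,35.51,141.06,0
29,82.92,96.00,32.22,35.50,140.44,0
30,83.66,96.00,32.21,35.41,136.53,0
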