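index,hr_bpm,spo2_pct,ambient_c,body_c,speed_cm_s,alert
1,72.70,95.98,32.20,36.17,0.60,0
2,74.25,96.44,32.22,36.04,0.50,0
3,76.00,96.92,32.24,35.92,0.44,0
4,77.55,97.29,32.26,35.84,0.42,0
5,78.60,97.47,32.28,35.79,0.41,0
6,79.04,97.47,32.30,35.77,0.41,0
7,78.91,97.36,32.32,35.75,0.38,0
8,78.45,97.21,32.34,35.74,0.34,0
9,77.93,97.10,32.35,35.72,0.31,0
10,77.55,97.04,32.37,35.72,0.30,0
11,77.38,97.01,32.38,35.72,0.31,0
12,77.35,97.00,32.39,35.72,0.33,0
13,77.39,97.00,32.40,35.73,0.34,0
14,77.41,97.00,32.41,35.73,0.36,0
15,77.33,97.00,32.42,35.73,0.37,0
16,77.10,97.00,32.43,35.73,0.38,0
17,76.74,97.00,32.44,35.74,0.39,0
18,76.39,97.00,32.45,35.74,0.39,0
19,76.26,97.00,32.47,35.75,0.40,0
20,76.48,97.00,32.48,35.74,0.41,0
21,76.95,97.00,32.49,35.73,0.45,0
22,77.50,97.00,32.51,35.71,0.51,0
23,78.00,97.00,32.52,35.69,0.58,0
24,78.40,97.00,32.52,35.68,0.63,0
25,78.66,97.00,32.53,35.66,0.67,0
26,78.73,97.00,32.54,35.64,0.68,0
27,78.61,97.00,32.55,35.62,0.67,0
28,78.42,97.00,32.56,35.61,0.65,0
29,78.32,97.00,32.58,35.60,0.62,0
30,78.41,97.00,32.59,35.59,0.58,0
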