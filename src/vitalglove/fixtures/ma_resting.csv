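index,hr_bpm,spo2_pct,ambient_c,body_c,speed_cm_s,alert
1,76.48,97.00,32.25,35.82,0.36,0
2,78.16,97.60,32.26,35.79,0.36,0
3,79.08,97.60,32.28,35.78,0.43,0
4,79.70,97.60,32.30,35.76,0.43,0
5,79.30,97.40,32.32,35.75,0.40,0
6,78.48,97.20,32.33,35.73,0.33,0
7,77.68,97.00,32.36,35.73,0.29,0
8,77.51,97.00,32.37,35.71,0.29,0
9,77.04,97.00,32.38,35.71,0.33,0
10,77.21,97.00,32.39,35.72,0.29,0
11,77.61,97.00,32.40,35.73,0.36,0
12,77.36,97.00,32.41,35.73,0.36,0
13,77.55,97.00,32.41,35.72,0.36,0
14,77.53,97.00,32.43,35.73,0.40,0
15,76.29,97.00,32.44,35.74,0.40,0
16,76.17,97.00,32.45,35.74,0.36,0
17,76.19,97.00,32.47,35.75,0.43,0
18,76.27,97.00,32.48,35.75,0.33,0
19,76.54,97.00,32.50,35.73,0.48,0
20,77.50,97.00,32.50,35.72,0.52,0
21,78.29,97.00,32.52,35.70,0.52,0
22,78.70,97.00,32.53,35.67,0.67,0
23,78.67,97.00,32.54,35.64,0.81,0
24,78.91,97.00,32.53,35.65,0.55,0
25,78.85,97.00,32.55,35.61,0.70,0
26,78.04,97.00,32.57,35.60,0.74,0
27,78.47,97.00,32.58,35.60,0.59,0
28,78.14,97.00,32.59,35.60,0.55,0
29,78.27,97.00,32.60,35.57,0.62,0
30,78.90,97.00,32.61,35.57,0.43,0
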