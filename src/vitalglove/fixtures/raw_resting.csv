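index,hr_bpm,spo2_pct,ambient_c,body_c,speed_cm_s,alert
1,67.31,95.0,32.09,36.95,1.29,0
2,73.46,95.0,32.23,35.89,0.37,0
3,74.21,97.0,32.23,35.83,0.18,0
4,75.25,97.0,32.25,35.85,0.18,0
5,79.82,98.0,32.25,35.77,0.54,0
6,79.67,98.0,32.31,35.77,0.54,0
7,81.83,98.0,32.27,35.75,0.37,0
8,78.82,97.0,32.31,35.77,0.54,0
9,78.34,97.0,32.35,35.75,0.18,0
10,77.85,97.0,32.35,35.69,0.36,0
11,75.54,97.0,32.39,35.67,0.18,0
12,77.87,97.0,32.39,35.75,0.18,0
13,77.96,97.0,32.39,35.71,0.54,0
14,75.98,97.0,32.39,35.75,0.37,0
15,78.72,97.0,32.41,35.71,0.18,0
16,77.51,97.0,32.41,35.75,0.54,0
17,76.62,97.0,32.43,35.71,0.18,0
18,78.91,97.0,32.41,35.69,0.54,0
19,75.88,97.0,32.47,35.81,0.54,0
20,72.51,97.0,32.47,35.75,0.18,0
21,76.94,97.0,32.45,35.75,0.37,0
22,76.73,97.0,32.53,35.77,0.54,0
23,79.28,97.0,32.49,35.69,0.01,0
24,77.25,97.0,32.55,35.67,1.30,0
25,77.31,97.0,32.49,35.71,0.37,0
26,80.88,97.0,32.53,35.67,0.37,0
27,78.77,97.0,32.57,35.63,1.29,0
28,79.13,97.0,32.55,35.53,0.72,0
29,78.46,97.0,32.53,35.69,0.01,0
30,76.99,97.0,32.57,35.55,1.12,0
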