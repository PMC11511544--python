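index,hr_bpm,spo2_pct,ambient_c,body_c,speed_cm_s,alert
1,84.0,96.0,33.39,35.63,0.23,0
2,72.61,96.0,33.43,35.67,4.70,0
3,109.53,96.0,33.39,35.63,25.73,0
4,67.79,96.0,33.39,35.23,1.41,0
5,82.98,96.0,33.35,34.21,18.33,0
6,82.98,96.0,33.31,34.17,29.18,0
7,79.07,96.0,33.27,34.71,32.96,0
8,85.55,96.0,33.25,34.71,0.37,0
9,95.56,95.0,33.21,34.55,13.06,0
10,107.52,95.0,33.19,34.53,40.27,0
11,88.26,96.0,33.19,34.59,20.66,0
12,76.15,96.0,33.09,34.31,34.42,0
13,77.84,96.0,33.11,34.17,42.66,0
14,123.78,96.0,33.07,34.09,42.87,0
15,61.86,96.0,32.99,34.31,31.23,0
16,65.46,96.0,32.97,34.37,21.79,0
17,65.46,96.0,32.89,34.47,24.88,0
18,68.76,97.0,32.87,34.51,38.45,0
19,85.09,97.0,32.85,34.23,44.25,0
20,82.09,97.0,32.83,34.43,48.92,0
21,82.09,97.0,32.79,34.33,41.70,0
22,72.16,97.0,32.79,34.07,15.17,0
23,72.18,97.0,32.77,34.39,21.44,0
24,72.18,97.0,32.73,34.25,61.90,0
25,61.52,97.0,32.67,33.95,53.51,0
26,64.47,97.0,32.67,34.31,22.53,0
27,64.47,97.0,32.61,34.31,17.63,0
28,62.9,97.0,32.61,34.39,49.50,0
29,62.9,97.0,32.57,34.37,62.94,0
30,84.73,97.0,32.57,34.25,1.82,0
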