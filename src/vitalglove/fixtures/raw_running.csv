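index,hr_bpm,spo2_pct,ambient_c,body_c,speed_cm_s,alert
1,73.04,97.0,32.63,36.41,0.36,0
2,77.6,97.0,32.67,36.41,14.36,0
3,77.6,97.0,32.69,36.25,41.65,0
4,89.65,97.0,32.67,36.23,41.80,0
5,126.0,97.0,32.67,35.91,64.25,0
6,97.8,97.0,32.65,35.75,264.14,0
7,111.68,97.0,32.65,35.85,133.73,0
8,79.42,97.0,32.67,36.01,72.56,0
9,76.08,96.0,32.65,35.97,94.56,0
10,73.7,96.0,32.63,35.83,243.92,0
11,73.93,93.0,32.61,35.81,169.97,0
12,109.79,93.0,32.59,35.59,112.85,0
13,141.98,96.0,32.57,35.45,125.20,0
14,95.27,96.0,32.57,35.47,224.25,0
15,149.34,96.0,32.53,35.19,64.61,0
16,160.32,96.0,32.49,35.39,113.97,1
17,152.36,96.0,32.53,35.61,182.78,1
18,144.88,96.0,32.47,35.35,263.09,0
19,148.05,96.0,32.45,35.53,131.04,0
20,126.0,96.0,32.43,35.19,274.35,0
21,146.5,96.0,32.41,35.05,128.31,0
22,144.71,96.0,32.39,35.27,194.79,0
23,158.34,96.0,32.37,35.53,140.80,1
24,158.42,96.0,32.37,35.27,164.90,1
25,149.04,96.0,32.33,34.85,99.93,0
26,137.48,96.0,32.33,35.05,247.58,0
27,129.2,96.0,32.27,34.81,104.30,0
28,125.22,96.0,32.25,35.21,292.72,0
29,78.3,96.0,32.27,35.39,46.21,0
30,74.52,96.0,32.25,35.61,204.08,0
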