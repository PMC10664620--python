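patient,cohort,dose,agt_activity,response
1,1,40,19.82,40.18
2,1,40,46.77,13.23
3,1,40,8.63,51.37
4,2,40,31.66,28.34
5,2,40,7.90,52.10
6,2,40,34.90,25.10
7,3,60,25.07,34.93
8,3,60,12.27,47.73
9,3,60,9.75,50.25
10,4,60,7.24,52.76
11,4,60,25.87,34.13
12,4,60,10.81,49.19
13,5,60,16.09,43.91
14,5,60,27.74,32.26
15,5,60,8.59,51.41
16,6,60,24.44,35.56
17,6,60,9.81,50.19
18,6,60,5.26,54.74
19,7,80,11.05,48.95
20,7,80,9.36,50.64
21,7,80,15.78,44.22
22,8,80,8.37,51.63
23,8,80,16.01,43.99
24,8,80,17.81,42.19
25,9,80,11.95,48.05
26,9,80,9.93,50.07
27,9,80,9.87,50.13
28,10,80,10.20,49.80
29,10,80,9.80,50.20
30,10,80,16.32,43.68
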