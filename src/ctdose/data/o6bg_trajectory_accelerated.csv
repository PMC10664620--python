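patient,cohort,dose,agt_activity,response
1,1,40,19.82,40.18
2,1,40,46.77,13.23
3,1,40,8.63,51.37
4,2,60,26.98,33.02
5,2,60,5.67,54.33
6,2,60,8.18,51.82
7,3,60,25.07,34.93
8,3,60,12.27,47.73
9,3,60,9.75,50.25
10,4,80,10.81,49.19
11,4,80,6.49,53.51
12,4,80,9.92,50.08
13,5,80,9.72,50.28
14,5,80,12.16,47.84
15,5,80,30.06,29.94
16,6,80,12.46,47.54
17,6,80,5.54,54.46
18,6,80,4.18,55.82
19,7,80,11.05,48.95
20,7,80,9.36,50.64
21,7,80,15.78,44.22
22,8,80,15.93,44.07
23,8,80,9.95,50.05
24,8,80,9.67,50.33
25,9,100,4.30,55.70
26,9,100,7.59,52.41
27,9,100,9.14,50.86
28,10,100,6.10,53.90
29,10,100,5.90,54.10
30,10,100,3.41,56.59
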