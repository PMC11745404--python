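cover,agb
74.66,104.259
52.36,39.187
23.17,9.171
31.77,18.816
30.28,24.919
37.06,17.739
76.12,102.41
8.63,2.415
35.49,19.824
75.18,106.983
72.07,89.147
57.38,48.323
12.42,5.642
34.19,11.98
82.73,134.902
92.92,187.851
67.18,74.751
15.28,5.401
83.46,143.891
15.38,9.237
32.24,17.676
33.56,13.792
36.87,27.455
11.02,13.093
17.62,1.973
71.72,88.625
7.21,15.97
37.31,23.206
0.27,0.1
43.85,17.104
8.25,15.291
3.25,0.1
77.15,96.876
19.6,17.203
77.06,112.421
25.49,13.933
76.05,106.883
41.99,25.96
63.73,66.81
92.56,202.899
19.71,12.037
59.96,54.959
7.9,10.032
44.18,24.842
15.33,10.099
72.82,81.029
10.17,4.638
42.23,34.336
6.75,5.634
44.83,26.391
84.24,142.86
73.11,97.264
45.04,25.221
87.51,176.003
46.55,32.392
24.55,15.627
13.49,21.833
77.68,124.242
14.27,5.547
61.61,54.536
81.93,130.418
24.63,14.363
71.43,94.262
11.13,2.897
3.51,5.795
64.22,57.281
41.01,34.547
90.36,193.219
88.91,160.783
71.92,89.952
74.33,96.147
64.97,68.141
71.99,90.483
28.97,15.649
90.96,193.0
74.61,97.441
79.36,127.589
2.87,11.928
23.02,0.1
30.08,22.793
83.67,142.566
52.65,33.596
64.35,63.109
48.13,36.493
44.35,36.401
42.86,35.324
51.12,36.087
82.17,132.503
79.98,129.605
89.11,177.149
75.84,101.414
4.75,0.1
26.9,18.19
28.7,17.761
11.5,5.348
91.97,197.695
80.9,117.139
41.11,28.81
7.35,15.175
37.07,28.671
19.39,5.072
36.25,16.625
43.61,25.016
94.35,214.83
41.36,29.02
6.24,11.8
34.42,14.742
44.48,26.417
29.86,8.685
9.2,21.991
93.86,206.222
7.39,15.168
69.4,82.026
51.81,42.098
79.1,121.483
64.51,61.258
6.15,12.322
2.64,0.1
8.24,4.842
64.27,72.919
14.68,10.376
15.07,1.318
35.75,16.356
1.98,1.343
91.38,204.214
67.16,73.189
60.75,56.898
74.98,104.374
94.96,230.194
12.06,7.633
75.9,105.403
79.8,115.309
49.0,35.806
26.26,2.641
74.8,102.182
15.14,13.731
93.7,205.961
24.06,9.487
77.2,105.473
63.41,53.342
59.4,59.547
65.53,63.638
4.28,0.1
7.4,3.488
62.96,65.925
57.31,45.33
20.51,13.329
83.3,139.144
81.5,129.42
75.27,102.014
11.88,15.537
81.76,139.248
36.98,27.319
76.74,108.508
71.71,85.198
59.21,48.098
54.07,55.342
48.82,41.555
49.85,35.757
54.25,46.847
93.31,211.056
3.06,15.463
80.86,136.234
87.67,152.929
69.67,87.872
84.96,147.745
41.69,26.625
66.49,64.673
52.59,37.53
31.76,15.207
21.65,15.547
84.11,139.674
12.83,0.1
80.97,126.67
93.41,206.833
45.51,27.597
22.37,14.134
56.01,36.738
57.73,38.165
39.09,24.633
69.68,83.753
79.19,124.555
71.09,87.292
4.73,14.091
87.23,160.039
28.84,26.337
86.42,168.614
30.13,18.362
65.86,69.298
38.67,18.776
59.99,56.548
72.1,85.765
74.85,102.35
57.51,57.765
55.9,50.943
45.35,21.565
63.16,53.934
77.26,118.114
5.25,9.872
25.39,22.57
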