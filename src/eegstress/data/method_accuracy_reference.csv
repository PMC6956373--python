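dataset,participant_id,pca_knn,all_features_knn,proposed
1,1,70.52,77.22,79.07
2,2,70.83,91.65,93.62
3,4,67.56,94.81,96.13
4,5,77.14,75.0,79.82
5,8,65.62,74.67,78.23
6,10,53.89,62.95,64.00
7,11,78.32,82.22,84.23
8,12,56.22,64.21,65.26
9,13,54.31,62.28,65.92
10,14,71.29,86.23,85.58
11,15,58.68,75.71,76.09
12,16,49.23,65.91,65.62
13,18,68.55,80.24,91.71
14,19,54.36,77.44,82.58
15,20,55.81,71.92,80.94
16,21,58.94,76.22,85.5
17,22,64.87,89.44,92.79
18,24,62.91,76.36,83.72
19,25,63.30,81.49,84.85
20,26,54.89,91.45,93.33
21,27,75.43,78.25,81.66
22,28,49.43,76,87.51
23,29,52.82,75.12,85.33
24,31,65.85,78.42,80.62
25,32,61.09,80.03,81.17
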