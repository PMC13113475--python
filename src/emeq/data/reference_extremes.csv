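diet_id,min_g_per_kg_dm,max_g_per_kg_dm
1,13.45,22.52
2,12.49,22.66
3,13.51,21.98
4,13.15,22.53
5,13.12,23.08
6,13.39,22.68
7,14.43,22.92
8,14.42,22.85
9,14.48,22.96
10,15.08,27.19
11,15.37,28.5
12,15.44,25.92
13,15.25,24.4
14,16.03,30.76
15,16.73,34.27
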