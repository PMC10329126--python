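# Failure times (per 1000 h) of 50 electronic machines.
# Transcribed from the primary source (Aryal & Elbatal); verified against
# published summary statistics (mean 3.343, median 1.414, variance 17.484,
# min 0.036, max 15.080, skewness 1.416, kurtosis 4.084).
0.036
0.058
0.061
0.074
0.078
0.086
0.102
0.103
0.114
0.116
0.148
0.183
0.192
0.254
0.262
0.379
0.381
0.538
0.570
0.574
0.590
0.618
0.645
0.961
1.228
1.600
2.006
2.054
2.804
3.058
3.076
3.147
3.625
3.704
3.931
4.073
4.393
4.534
4.893
6.274
6.816
7.896
7.904
8.022
9.337
10.940
11.020
13.880
14.730
15.080
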