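# Failure times of 23 secondary reactor pumps (thousands of hours).
# Transcribed from the primary source (El-Desouky, Mustafa & Al-Garash);
# verified against published summary statistics (mean 1.578, median 0.614,
# variance 3.727, min 0.062, max 6.560, skewness 1.364, kurtosis 3.544).
2.160
0.746
0.402
0.954
0.491
6.560
4.992
0.347
0.150
0.358
0.101
1.359
3.465
1.060
0.614
1.921
4.082
0.199
0.605
0.273
0.070
0.062
5.320
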