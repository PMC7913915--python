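# sucrose freezing point depression, v1
# g sucrose per 100 g water, FPD degC
se_g_per_100g_water,fpd_c
0.0,0.00000
5.0,0.27585
10.0,0.56001
15.0,0.85234
20.0,1.15269
25.0,1.46093
30.0,1.77691
35.0,2.10050
40.0,2.43156
45.0,2.76996
50.0,3.11557
55.0,3.46827
60.0,3.82792
65.0,4.19439
70.0,4.56758
75.0,4.94735
80.0,5.33359
85.0,5.72618
90.0,6.12501
95.0,6.52996
100.0,6.94092
105.0,7.35778
110.0,7.78044
115.0,8.20879
120.0,8.64272
125.0,9.08213
130.0,9.52691
135.0,9.97699
140.0,10.43224
145.0,10.89258
150.0,11.35791
155.0,11.82815
160.0,12.30319
165.0,12.78295
170.0,13.26734
175.0,13.75627
180.0,14.24966
185.0,14.74743
190.0,15.24949
195.0,15.75576
200.0,16.26617
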