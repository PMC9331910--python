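sample_number,e_l,e_w,e_h,v_true,v_gm,v_ch,v_as,v_vb,v_pb
1,0.24,0.02,-0.39,583.57,2470.26,1478.09,652.76,1031.63,643.75
2,0.19,0.17,0.09,825.26,4183.38,1642.80,1006.54,966.07,881.53
3,0.01,0.13,0.22,599.71,3226.55,1480.40,653.73,1188.59,649.34
4,0.16,0.33,0.21,606.27,3228.54,1476.01,788.70,1220.57,673.46
5,-0.28,0.39,-0.32,764.41,3602.84,1581.10,1073.00,1106.77,817.86
6,0.15,0,0.06,657.79,1837.55,1379.45,844.41,1124.53,719.26
7,-0.03,0.26,0.04,751.52,3735.58,1673.22,932.01,1011.26,803.42
8,0.12,-0.13,0.05,642.60,3620.73,1434.24,652.15,954.61,711.38
9,0.33,-0.10,0.22,738.57,3905.98,1602.23,894.01,1420.82,779.482
10,0.05,-0.11,0.03,862.75,4483.76,1925.40,1130.54,1597.80,934.18
11,-0.23,0.17,0.05,649.79,3521.60,1373.24,871.27,1182.27,709.47
12,-0.30,0.11,0.02,588.59,2192.16,1248.59,516.18,843.26,636.43
13,-0.17,0.16,0.36,666.62,3677.26,1631.06,921.38,1229.84,725.49
14,0.03,0.15,-0.12,862.94,4298.38,1808.92,986.29,1410.73,918.53
15,0.24,0.35,0.33,619.21,3333.75,1614.49,732.54,1037.84,681.97
16,0.30,0.03,0,619.14,2288.87,1248.59,716.18,841.70,662.74
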