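Name: Sesquiterpene-A
RT: 7.1
RI: 777.1
Num Peaks: 7
61.94770 192.845
77.15030 217.896
94.04780 999
110.00100 662.445
121.94430 430.061
158.04880 132.881
208.00260 700.764

Name: Sesquiterpene-B
RT: 8.3
RI: 845.7
Num Peaks: 8
57.02940 408.686
59.94280 999
61.01890 345.027
85.05720 542.792
113.05930 687.271
113.98640 565.498
148.93340 272.633
213.14130 273.145

Name: Bornyl-chloride-like
RT: 8.9
RI: 880
Num Peaks: 9
71.21130 470.297
80.12590 684.383
81.01870 486.4
94.94220 413.22
105.96300 573.367
131.18370 999
181.16780 853.272
217.12010 287.745
267.21220 878.08

Name: Terpenoid-C
RT: 9.6
RI: 920
Num Peaks: 8
71.97210 138.382
74.92470 840.602
217.20460 103.1
296.05230 530.181
330.94270 483.519
367.15290 239.575
396.16690 999
432.10710 170.58

Name: Terpenoid-D
RT: 10.9
RI: 994.3
Num Peaks: 9
83.16360 149.874
91.18590 245.205
183.12070 999
226.15440 203.774
290.19850 461.982
319.05380 318.292
383.07580 678.316
398.03900 134.013
427.09620 499.912

Name: Terpenoid-E
RT: 12.2
RI: 1068.6
Num Peaks: 7
88.95150 526.777
100.12250 999
108.05940 234.419
128.15630 229.93
185.95250 442.679
264.97540 636.085
315.24970 511.097

Name: Hexahydroindene-F
RT: 13.5
RI: 1142.9
Num Peaks: 6
79.21520 563.251
94.94900 999
348.14050 569.954
362.03490 532.309
391.03580 586.049
405.92980 636.735

Name: Phenanthrene-like
RT: 23.1
RI: 1691.4
Num Peaks: 7
56.92360 113.604
67.21940 503.127
93.09380 321.696
136.11130 261.913
165.10430 416.32
244.21930 879.489
286.97960 999

Name: PCB-like-052
RT: 26.2
RI: 1868.6
Num Peaks: 9
70.16320 747.53
106.93360 358.803
187.20750 649.234
202.14940 663.266
230.94630 256.421
281.05820 669.458
331.04710 783.383
360.24700 632.821
403.10220 999

Name: MHC-1-like
RT: 28
RI: 1971.4
Num Peaks: 6
102.02640 406.871
110.21140 130.653
242.23240 426.435
270.17480 374.114
334.04780 439.975
377.03400 999

Name: Fluoranthene-like
RT: 28.5
RI: 2000
Num Peaks: 8
53.10790 854.685
57.18740 614.118
58.06480 615.48
121.13820 425.784
130.07070 458
156.11570 999
185.02520 102.862
228.16020 438.048

Name: Q1-like
RT: 29.1
RI: 2034.3
Num Peaks: 7
77.99870 451.823
84.04930 486.707
105.96420 317.701
120.12470 999
135.21140 125.023
163.03100 669.528
213.16780 878.314

Name: PCB-like-101
RT: 29.5
RI: 2057.1
Num Peaks: 9
96.12600 999
98.09810 503.725
200.94210 786.949
236.02790 81.3428
265.20260 563.103
280.03940 498.598
323.11840 782.033
359.10740 752.966
387.07060 116.231

Name: Pyrene-like
RT: 29.7
RI: 2068.6
Num Peaks: 9
54.97750 801.343
60.99510 749.545
63.98570 673.094
83.10420 93.169
98.20320 999
117.00800 588.466
129.06470 93.5297
161.92570 587.894
205.04660 420.833

Name: DDE-like
RT: 30.6
RI: 2120
Num Peaks: 8
106.15510 519.497
109.97320 882.895
265.94600 81.4772
315.98050 999
330.06920 770.241
380.22650 748.418
395.18230 862.159
410.18540 711.242

Name: PCB-like-118
RT: 31.8
RI: 2188.6
Num Peaks: 8
68.97530 464.818
109.03830 290.098
155.18580 509.633
190.18690 999
217.95260 589.627
253.21900 778.506
317.22370 562.768
344.94460 501.665

Name: DDD-like
RT: 32.2
RI: 2211.4
Num Peaks: 7
56.01420 694.746
87.20040 362.739
91.98190 999
114.93770 593.952
171.18880 313.692
213.99540 89.8915
278.18900 274.67

Name: PCB-like-153
RT: 32.7
RI: 2240
Num Peaks: 6
93.20590 422.917
111.05360 730.14
256.02630 385.834
291.20090 723.734
334.20070 999
413.06460 446.699

Name: DDT-like
RT: 33.5
RI: 2285.7
Num Peaks: 8
76.05210 518.585
97.04260 107.368
113.10470 999
140.96590 509.505
191.22120 487.564
220.08920 380.666
249.06170 804.223
313.21990 468.785

Name: PCB-like-138
RT: 33.9
RI: 2308.6
Num Peaks: 7
64.04620 530.273
76.09440 474.463
108.21580 697.199
136.14330 791.137
199.95400 999
278.95970 679.93
358.10930 830.637

Name: PCB-like-187
RT: 34.4
RI: 2337.1
Num Peaks: 8
108.03650 821.973
116.24010 673.797
179.14620 181.643
193.06480 163.99
228.21870 750.111
242.17410 216.083
321.05460 999
400.11850 119.62

Name: BDE-like-047
RT: 35.8
RI: 2417.1
Num Peaks: 6
98.09590 779.791
99.97880 435.884
272.92820 164.883
302.21570 522.348
331.14090 412.213
366.04320 999

Name: PCB-like-180
RT: 36
RI: 2428.6
Num Peaks: 8
77.95640 999
102.00020 492.892
287.96790 421.359
302.05510 737.554
330.18600 447.395
358.96560 522.875
387.15710 784.886
422.02600 827.258

Name: Sterol-like-A
RT: 36.4
RI: 2451.4
Num Peaks: 7
98.24330 361.808
123.10900 861.305
223.98950 795.757
252.94590 697.295
317.10160 999
353.22900 706.6
368.12920 419.828

Name: PCB-like-170
RT: 37
RI: 2485.7
Num Peaks: 9
100.06530 122.063
110.98800 110.366
111.98170 592.922
117.22420 309.238
139.95470 999
218.99970 185.474
247.10260 860.67
297.07160 885.206
347.09040 253.479

Name: MeO-BDE-like-068
RT: 37.4
RI: 2508.6
Num Peaks: 6
99.22260 705.064
123.09990 461.554
128.13570 866.621
157.08440 999
192.14280 538.864
220.19880 170.526

Name: Sterol-like-B
RT: 37.9
RI: 2537.1
Num Peaks: 8
80.07100 305.823
122.94640 999
124.99750 663.105
204.24800 577.966
247.13840 386.857
261.18280 552.692
289.07020 560.803
324.20800 447.584

Name: BDE-like-099
RT: 39.8
RI: 2645.7
Num Peaks: 7
59.14200 246.657
89.93380 999
106.13500 503.565
120.18770 777.653
134.11010 441.724
162.04660 425.524
176.12350 494.842

Name: Cholestadiene-like
RT: 39.9
RI: 2651.4
Num Peaks: 6
84.13250 408.707
109.01090 514.404
132.04240 636.627
145.97170 737.554
160.22840 999
196.18510 241.922

Name: BDE-like-153
RT: 43.3
RI: 2845.7
Num Peaks: 8
63.98510 677.808
81.18640 999
126.24320 776.408
176.06090 571.563
254.98190 895.159
283.15090 481.712
311.24490 187.144
361.06670 877.664

Name: Sporadic-X
RT: 14.8
RI: 1217.1
Num Peaks: 7
64.15690 688.882
83.07260 95.0789
212.97550 361.109
256.18400 999
271.22390 600.237
314.24890 311.15
342.97520 869.203

Name: Sporadic-Y
RT: 24.3
RI: 1760
Num Peaks: 8
123.23530 320.945
127.07910 509.902
187.95650 853.529
266.92410 888.866
295.19170 613.156
330.19160 216.607
358.09900 470.422
422.05540 999

Name: BHT-like-antioxidant
RT: 9.95
RI: 940
Num Peaks: 6
53.96250 864.262
94.17020 437.484
220.94620 999
256.07850 89.3005
285.18580 279.657
349.18540 525.099

Name: Alkylphenol-antioxidant
RT: 16.4
RI: 1308.6
Num Peaks: 6
65.02270 465.306
89.08770 207.665
125.14760 999
204.09540 533.639
283.12570 448.238
297.05400 516.294

Name: VS-13C-CB-097
RT: 26.8
RI: 1902.9
Num Peaks: 8
72.06510 547.719
101.00100 299.397
104.04500 626.927
109.92620 382.353
116.09060 635.676
118.21890 834.026
128.11810 999
197.07330 803.346

Name: VS-13C-CB-188
RT: 35.2
RI: 2382.9
Num Peaks: 6
88.17090 564.409
104.04870 573.071
231.94680 750.289
311.22200 999
390.11330 123.665
405.01980 899.972

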