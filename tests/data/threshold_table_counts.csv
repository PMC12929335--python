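statistic,phase,threshold,ba,sens,sens_num,sens_den,spec,spec_num,spec_den,ppv,ppv_num,ppv_den,npv,npv_num,npv_den
L,arterial,40,67.8,35.6,21,59,100,1505,1505,100,21,21,97.5,1505,1543
L,arterial,45,81.4,62.7,37,59,100,1505,1505,100,37,37,98.6,1505,1527
L,arterial,50,91.7,84.7,50,59,98.7,1486,1505,72.5,50,69,99.4,1486,1495
L,arterial,55,93.4,91.5,54,59,95.3,1434,1505,43.2,54,125,99.7,1434,1439
L,arterial,60,91.2,94.9,56,59,87.4,1316,1505,22.9,56,245,99.8,1316,1319
L,arterial,65,83.8,96.6,57,59,70.9,1067,1505,11.5,57,495,99.8,1067,1069
L,arterial,70,72.4,98.3,58,59,46.4,699,1505,6.7,58,864,99.9,699,700
L,venous,70,78.8,60,45,75,97.5,119,122,93.8,45,48,79.9,119,149
L,venous,75,85.4,73.3,55,75,97.5,119,122,94.8,55,58,85.6,119,139
L,venous,80,88.2,81.3,61,75,95.1,116,122,91,61,67,89.2,116,130
L,venous,85,92.0,94.7,71,75,89.3,109,122,84.5,71,84,96.5,109,113
L,venous,90,88.3,94.7,71,75,82,100,122,76.3,71,93,96.2,100,104
L,venous,95,85.6,97.3,73,75,73.8,90,122,69.5,73,105,97.8,90,92
L,venous,100,78.6,97.3,73,75,59.8,73,122,59.8,73,122,97.3,73,75
L,delayed,45,69.2,38.5,30,78,100,133,133,100,30,30,73.5,133,181
L,delayed,50,78.2,56.4,44,78,100,133,133,100,44,44,79.6,133,167
L,delayed,55,95.1,91,71,78,99.2,132,133,98.6,71,72,95,132,139
L,delayed,60,96.8,97.4,76,78,96.2,128,133,93.8,76,81,98.5,128,130
L,delayed,65,94.0,100,78,78,88,117,133,83,78,94,100,117,117
L,delayed,70,86.5,100,78,78,72.9,97,133,68.4,78,114,100,97,97
L,delayed,75,81.2,100,78,78,62.4,83,133,60.9,78,128,100,83,83
L-S,non-contrast,-15,63.3,26.5,35,132,100,1608,1608,100,35,35,94.3,1608,1705
L-S,non-contrast,-10,69.3,38.6,51,132,99.9,1607,1608,98.1,51,52,95.2,1607,1688
L-S,non-contrast,-5,81.9,64.4,85,132,99.4,1598,1608,89.5,85,95,97.1,1598,1645
L-S,non-contrast,0,88.3,78.8,104,132,97.8,1572,1608,74.3,104,140,98.2,1572,1600
L-S,non-contrast,5,90.6,88.6,117,132,92.5,1488,1608,49.4,117,237,99,1488,1503
L-S,non-contrast,10,86.2,97,128,132,75.4,1213,1608,24.5,128,523,99.7,1213,1217
L-S,non-contrast,15,68.9,98.5,130,132,39.2,631,1608,11.7,130,1107,99.7,631,633
L-S,arterial,-55,62.1,33.9,20,59,90.4,1360,1505,12.1,20,165,97.2,1360,1399
L-S,arterial,-50,68.7,52.5,31,59,84.9,1278,1505,12,31,258,97.9,1278,1306
L-S,arterial,-45,68.5,59.3,35,59,77.7,1170,1505,9.5,35,370,98,1170,1194
L-S,arterial,-40,71.1,74.6,44,59,67.6,1017,1505,8.3,44,532,98.5,1017,1032
L-S,arterial,-35,69.5,81.4,48,59,57.6,867,1505,7,48,686,98.7,867,878
L-S,arterial,-30,64.3,84.7,50,59,43.9,660,1505,5.6,50,895,98.7,660,669
L-S,arterial,-25,60.8,89.8,53,59,31.8,478,1505,4.9,53,1080,98.8,478,484
L-S,venous,-30,63.4,54.7,41,75,72.1,88,122,54.7,41,75,72.1,88,122
L-S,venous,-25,63.5,61.3,46,75,65.6,80,122,52.3,46,88,73.4,80,109
L-S,venous,-20,68.8,78.7,59,75,59,72,122,54.1,59,109,81.8,72,88
L-S,venous,-15,71.4,92,69,75,50.8,62,122,53.5,69,129,91.2,62,68
L-S,venous,-10,70.4,97.3,73,75,43.4,53,122,51.4,73,142,96.4,53,55
L-S,venous,-5,65.7,98.7,74,75,32.8,40,122,47.4,74,156,97.6,40,41
L-S,venous,0,61.6,98.7,74,75,24.6,30,122,44.6,74,166,96.8,30,31
L-S,delayed,-15,68.5,38.5,30,78,98.5,131,133,93.8,30,32,73.2,131,179
L-S,delayed,-10,76.7,56.4,44,78,97,129,133,91.7,44,48,79.1,129,163
L-S,delayed,-5,85.1,76.9,60,78,93.2,124,133,87,60,69,87.3,124,142
L-S,delayed,0,86.8,87.2,68,78,86.5,115,133,79.1,68,86,92,115,125
L-S,delayed,5,83.5,94.9,74,78,72.2,96,133,66.7,74,111,96,96,100
L-S,delayed,10,72.8,97.4,76,78,48.1,64,133,52.4,76,145,97,64,66
L-S,delayed,15,60.6,98.7,77,78,22.6,30,133,42.8,77,180,96.8,30,31
L/S,non-contrast,0.8,75.7,51.5,68,132,99.9,1607,1608,98.6,68,69,96.2,1607,1671
L/S,non-contrast,0.9,84.5,69.7,92,132,99.3,1597,1608,89.3,92,103,97.6,1597,1637
L/S,non-contrast,1,88.3,78.8,104,132,97.8,1572,1608,74.3,104,140,98.2,1572,1600
L/S,non-contrast,1.1,89.8,86.4,114,132,93.2,1498,1608,50.9,114,224,98.8,1498,1516
L/S,non-contrast,1.2,85.9,93.2,123,132,78.5,1263,1608,26.3,123,468,99.3,1263,1272
L/S,non-contrast,1.3,73.0,95.5,126,132,50.6,813,1608,13.7,126,921,99.3,813,819
L/S,arterial,0.3,56.8,13.6,8,59,100,1505,1505,100,8,8,96.7,1505,1556
L/S,arterial,0.4,63.6,27.1,16,59,100,1505,1505,100,16,16,97.2,1505,1548
L/S,arterial,0.5,81.1,64.4,38,59,97.9,1473,1505,54.3,38,70,98.6,1473,1494
L/S,arterial,0.6,82.5,86.4,51,59,78.6,1183,1505,13.7,51,373,99.3,1183,1191
L/S,arterial,0.7,67.8,93.2,55,59,42.5,639,1505,6,55,921,99.4,639,643
L/S,arterial,0.8,57.1,98.3,58,59,15.9,240,1505,4.4,58,1323,99.6,240,241
L/S,venous,0.5,56.7,13.3,10,75,100,122,122,100,10,10,65.2,122,187
L/S,venous,0.6,64.3,29.3,22,75,99.2,121,122,95.7,22,23,69.5,121,174
L/S,venous,0.7,71.4,56,42,75,86.9,106,122,72.4,42,58,76.3,106,139
L/S,venous,0.8,77.3,86.7,65,75,68,83,122,62.5,65,104,89.2,83,93
L/S,venous,0.9,70.6,98.7,74,75,42.6,52,122,51.4,74,144,98.1,52,53
L/S,venous,1,61.6,98.7,74,75,24.6,30,122,44.6,74,166,96.8,30,31
L/S,delayed,0.7,62.8,25.6,20,78,100,133,133,100,20,20,69.6,133,191
L/S,delayed,0.8,72.3,46.2,36,78,98.5,131,133,94.7,36,38,75.7,131,173
L/S,delayed,0.9,85.8,76.9,60,78,94.7,126,133,89.6,60,67,87.5,126,144
L/S,delayed,1,86.8,87.2,68,78,86.5,115,133,79.1,68,86,92,115,125
L/S,delayed,1.1,77.5,94.9,74,78,60.2,80,133,58.3,74,127,95.2,80,84
L/S,delayed,1.2,61.6,96.2,75,78,27.1,36,133,43.6,75,172,92.3,36,39
FF,non-contrast,5,78.9,57.7,928,1608,100,132,132,100,928,928,16.3,132,812
FF,non-contrast,10,94.9,89.8,1444,1608,100,132,132,100,1444,1444,44.6,132,296
FF,non-contrast,15,100.0,100,1608,1608,100,132,132,100,1608,1608,100,132,132
FF,non-contrast,20,74.2,100,1608,1608,48.5,64,132,95.9,1608,1676,100,64,64
FF,arterial,5,78.7,59.1,890,1505,98.3,58,59,99.9,890,891,8.6,58,673
FF,arterial,10,92.7,95.6,1439,1505,89.8,53,59,99.6,1439,1445,44.5,53,119
FF,arterial,15,78.0,100,1505,1505,55.9,33,59,98.3,1505,1531,100,33,33
FF,arterial,20,63.6,100,1505,1505,27.1,16,59,97.2,1505,1548,100,16,16
FF,venous,5,61.1,22.1,27,122,100,75,75,100,27,27,44.1,75,170
FF,venous,10,83.1,68.9,84,122,97.3,73,75,97.7,84,86,65.8,73,111
FF,venous,15,85.7,96.7,118,122,74.7,56,75,86.1,118,137,93.3,56,60
FF,venous,20,70.3,99.2,121,122,41.3,31,75,73.3,121,165,96.9,31,32
FF,delayed,5,62.4,24.8,33,133,100,78,78,100,33,33,43.8,78,178
FF,delayed,10,84.6,69.2,92,133,100,78,78,100,92,92,65.5,78,119
FF,delayed,15,95.4,98.5,131,133,92.3,72,78,95.6,131,137,97.3,72,74
FF,delayed,20,69.2,100,133,133,38.5,30,78,73.5,133,181,100,30,30
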