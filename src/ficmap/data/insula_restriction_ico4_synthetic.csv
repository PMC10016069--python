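vertex_index
8
24
32
78
79
80
93
95
98
114
116
118
282
283
284
285
286
288
290
326
328
340
342
343
344
353
355
362
363
364
365
432
433
434
440
441
442
443
444
449
450
451
452
453
454
455
1075
1077
1078
1080
1082
1083
1084
1085
1086
1088
1090
1091
1092
1094
1096
1098
1099
1100
1101
1102
1103
1240
1241
1242
1246
1247
1248
1249
1266
1298
1299
1300
1301
1303
1306
1307
1308
1309
1310
1311
1312
1313
1314
1315
1316
1317
1319
1320
1321
1323
1327
1359
1361
1362
1363
1368
1369
1370
1371
1393
1394
1395
1396
1397
1398
1399
1400
1401
1402
1403
1404
1405
1406
1407
1408
1409
1686
1687
1688
1689
1690
1691
1692
1693
1694
1695
1697
1699
1704
1714
1715
1716
1717
1718
1719
1720
1721
1722
1723
1724
1725
1726
1727
1728
1729
1730
1731
1732
1733
1734
1735
1740
1742
1752
1754
1755
1758
1759
1760
1761
1762
1763
1764
1765
1767
1770
1771
1772
1773
1774
1775
1777
1778
1780
1781
1782
1783
1784
1785
1786
1787
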