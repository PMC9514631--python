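year,calf,adult_female,adult_male,total,ci_low,ci_high
2005,1658,3188,3315,8160,6090,11410
2006,1237,3638,3965,8840,6790,11910
2007,913,3147,2801,6860,5320,9100
2008,1334,3704,2852,7890,6080,10600
2009,1110,3469,3261,7840,6260,10040
2010,756,2701,2242,5700,4540,7350
2011,626,2606,1668,4900,3870,6380
2012,624,1734,1872,4230,3250,5710
2013,356,1078,1326,2760,2160,3650
2014,714,1623,2013,4350,3220,6210
2015,439,1513,1498,3450,2610,4770
2016,689,1641,1690,4020,3230,5180
2017,588,1634,1487,3710,3010,4710
2018,428,1157,1446,3030,2320,4140
2019,539,1633,2008,4180,3250,5580
2020,502,1394,1254,3150,2400,4320
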