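year,study,deaths,at_risk
2005,Lenarz,13,51
2006,Lenarz,10,32
2007,Lenarz,10,57
2010,VoyageursNP,0,11
2010,GrandPortage,2,10
2011,VoyageursNP,2,19
2011,GrandPortage,5,15
2012,VoyageursNP,3,19
2012,GrandPortage,0,12
2013,Carstensen,20,105
2013,VoyageursNP,0,14
2013,GrandPortage,9,22
2014,Carstensen,12,101
2014,VoyageursNP,1,14
2014,GrandPortage,4,28
2015,Carstensen,14,93
2015,VoyageursNP,2,11
2015,GrandPortage,8,38
2016,Carstensen,8,57
2016,VoyageursNP,1,5
2016,GrandPortage,3,36
2017,VoyageursNP,1,4
2017,GrandPortage,4,31
2018,GrandPortage,4,28
2019,GrandPortage,2,29
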