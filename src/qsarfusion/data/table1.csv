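id,ic50_nM,Best_train,Fast_train,Caesar_train
CHEMBL195041,2.3,15,9.9,1129
CHEMBL193990,6.6,6.8,6.2,942
CHEMBL248935,14,20,20,833
CHEMBL195320,18,8.5,6.2,942
CHEMBL176164,23,19,23,1151
CHEMBL250765,37,30,22,950
CHEMBL362677,47,23,23,1153
CHEMBL249959,70,110,20,1000
CHEMBL250992,72,47,6.9,72
CHEMBL251155,110,220,23,756
CHEMBL588536,270,670,790,78578
CHEMBL400772,470,2200,268,231
CHEMBL367390,640,2000,2237,1028
CHEMBL608262,830,1200,1456,94262
CHEMBL401105,900,1000,235,20
CHEMBL176115,1100,970,1044,1449
CHEMBL253542,1200,1100,189,3.8
CHEMBL592490,1800,860,1275,93360
CHEMBL589090,6700,1700,1419,3561
CHEMBL199299,15000,22000,233,1745
CHEMBL251629,19000,3600,615,411
CHEMBL259084,28000,6800,31827,5300
CHEMBL251628,37000,63000,1360,24786
CHEMBL438485,50000,16000,320,243
CHEMBL589501,100000,160000,48276,96926
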