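id,ic50_nM,BB,BF,BC,FB,FF,FC
CHEMBL195177,3.4,3.9,5.2,5.1,14.8,6.2,12.3
CHEMBL359881,4.4,12.0,46.1,42.3,17.3,22.5,29.4
CHEMBL179717,4.5,9.0,42.1,43.2,14.3,21.9,29.3
CHEMBL175553,5.5,11.2,57.8,43.1,17.6,20.5,29.1
CHEMBL192161,7,183.4,74.6,36.7,258.7,253.9,291.4
CHEMBL191969,8.2,6.4,15.3,14.3,10.5,9.4,13.5
CHEMBL175472,9.8,7.9,48.4,9.9,12.4,22.5,29.1
CHEMBL361378,12,9.9,48.1,43.7,14.7,21.7,29.3
CHEMBL362255,12,11.9,55.4,42.3,15.5,22.9,29.4
CHEMBL369254,12,70.2,51.3,45.6,38.0,23.7,31.5
CHEMBL364978,13,4.8,4.9,5.1,13.5,6.5,12.3
CHEMBL195846,14,3.9,5.0,5.1,12.8,6.2,12.3
CHEMBL179583,16,12.2,48.5,43.1,13.4,23.2,28.9
CHEMBL178972,17,15.9,52.5,43.1,18.0,23.3,29.1
CHEMBL250360,23,19.8,46.8,43.7,17.6,21.7,29.4
CHEMBL175879,24,21.6,57.0,42.3,24.0,23.2,29.2
CHEMBL179267,31,7.4,63.5,42.8,20.5,21.2,29.4
CHEMBL192022,32,20.3,47.5,42.6,23.9,22.4,29.4
CHEMBL250158,39,10.1,20.4,43.7,19.1,21.5,29.3
CHEMBL363339,41,10.1,59.8,42.2,18.1,24.0,29.5
CHEMBL250555,45,26.3,48.2,42.9,24.5,22.7,29.4
CHEMBL250359,52,3.7,5.2,3.5,20.6,7.0,28.8
CHEMBL251585,52,4.5,3.0,3.1,11.9,4.9,10.7
CHEMBL398529,53,23.0,48.4,43.5,21.4,22.4,29.4
CHEMBL178971,55,62.4,44.9,43.1,41.7,22.1,29.3
CHEMBL427879,55,13.7,45.4,42.4,16.9,19.9,29.5
CHEMBL250963,57,8.6,44.1,42.9,17.8,21.5,27.2
CHEMBL251170,60,51.3,45.3,43.1,26.3,21.5,29.4
CHEMBL250759,61,45.6,47.4,43.3,36.6,23.2,29.5
CHEMBL367263,61,19.7,50.3,9.6,17.3,23.9,29.1
CHEMBL250159,67,55.7,45.3,43.1,25.7,17.2,29.4
CHEMBL398467,70,11.4,46.5,42.7,21.0,20.4,29.4
CHEMBL250796,73,3.3,3.4,4.2,14.7,6.0,14.4
CHEMBL250957,74,36.1,44.9,43.7,30.5,20.4,29.5
CHEMBL206609,77,25.9,51.0,44.0,9.6,16.3,17.8
CHEMBL400755,78,8.8,26.6,43.0,12.9,22.5,29.4
CHEMBL249569,80,11.1,48.3,43.3,17.0,22.9,28.0
CHEMBL193397,81,9.9,43.8,42.8,14.5,21.2,28.4
CHEMBL438868,82,18.9,42.0,43.1,13.1,19.0,29.3
CHEMBL249566,86,17.6,48.8,43.1,23.5,22.8,29.6
CHEMBL249345,90,23.2,47.6,43.0,20.9,20.0,25.0
CHEMBL399146,90,29.8,47.9,42.7,28.4,22.1,29.3
CHEMBL602931,92,483.6,560.1,506.8,645.9,594.0,588.2
CHEMBL249347,95,10.1,46.3,43.1,27.2,20.1,29.2
CHEMBL193476,100,951.1,914.5,925.8,2435.2,1027.4,1981.9
CHEMBL250361,100,14.2,6.6,14.5,14.9,20.9,29.6
CHEMBL248934,109,20.0,52.5,43.3,14.0,22.4,29.4
CHEMBL249750,110,12.7,49.3,43.5,20.7,21.6,29.3
CHEMBL208463,133,10.4,46.0,41.0,968.6,2768.3,2670.7
CHEMBL250566,140,5.2,17.3,26.3,18.4,20.9,29.6
CHEMBL251256,140,936.4,2453.5,2240.6,192.6,215.1,215.5
CHEMBL437331,142,471.8,521.6,450.6,64.2,222.1,60.7
CHEMBL249541,157,23.8,42.5,43.0,16.0,18.8,29.3
CHEMBL249776,158,13.9,47.2,43.7,16.7,20.9,29.4
CHEMBL249350,174,30.6,51.2,43.4,22.5,23.3,29.4
CHEMBL249546,176,10.6,47.3,42.8,17.9,21.0,29.4
CHEMBL251364,176,21.7,43.9,43.1,17.8,19.7,29.1
CHEMBL399933,180,14.8,45.0,43.5,20.8,18.9,29.4
CHEMBL400287,180,19.3,45.5,43.5,21.5,19.8,29.4
CHEMBL175780,200,61.7,47.5,42.3,36.0,21.9,29.5
CHEMBL176326,200,935.6,926.3,913.6,1896.0,986.2,1980.7
CHEMBL590335,210,791.5,721.8,807.4,616.3,639.0,644.7
CHEMBL398561,220,575.1,926.2,571.5,209.1,278.3,287.9
CHEMBL249777,231,15.0,45.7,42.5,25.5,21.7,29.4
CHEMBL442282,233,13.9,46.9,42.3,21.5,22.5,29.4
CHEMBL195599,250,981.5,908.0,925.8,2266.7,1057.6,1981.9
CHEMBL176015,290,54.1,52.8,54.4,24.0,29.3,28.0
CHEMBL251284,310,484.8,429.7,533.7,189.6,196.8,217.4
CHEMBL600441,310,454.6,559.9,516.5,300.5,513.5,254.1
CHEMBL599581,410,594.7,496.6,509.1,506.1,252.9,299.2
CHEMBL592784,420,462.2,492.0,475.1,216.7,203.8,198.3
CHEMBL1197465,580,2492.8,8163.9,5925.9,995.1,896.8,488.9
CHEMBL590809,600,492.4,539.0,534.3,816.4,536.2,549.3
CHEMBL1197456,610,2871.8,7537.6,6733.2,615.7,4139.2,3514.6
CHEMBL590637,610,1251.9,1786.7,1121.1,2379.0,1650.9,1262.3
CHEMBL591518,680,1797.9,1804.0,1516.5,6075.0,4714.4,2726.5
CHEMBL598973,700,12585.6,151896.0,84151.4,1047.3,396.5,1318.1
CHEMBL251368,710,27.7,45.9,43.8,13.4,21.2,29.1
CHEMBL1197303,800,5153.6,36481.1,6594.4,1277.8,681.9,4077.9
CHEMBL1197320,890,2537.8,7191.1,6002.7,1559.4,517.5,420.0
CHEMBL1197528,960,2752.7,7737.1,5925.9,765.7,654.9,559.0
CHEMBL215803,1000,3760.6,140257.0,74847.0,9672.7,50053.5,49263.9
CHEMBL253324,1000,996.2,2416.5,603.1,264.7,553.1,272.4
CHEMBL589347,1100,458.3,560.2,482.3,209.7,299.1,196.7
CHEMBL604784,1100,1188.4,1365.6,1205.7,2305.3,1962.3,1307.9
CHEMBL1197529,1120,2047.4,11678.5,8090.0,3368.8,3648.8,3659.9
CHEMBL1197326,1130,12645.5,45428.8,7432.7,1138.2,465.0,416.0
CHEMBL176041,1200,925.0,906.8,913.6,1933.6,1040.0,1980.7
CHEMBL590079,1350,548.9,548.5,550.6,1000.9,860.3,855.1
CHEMBL605083,1400,489.2,613.8,554.4,1224.9,1401.0,1345.6
CHEMBL175481,1500,69.2,57.7,49.2,1853.9,1526.1,1852.1
CHEMBL205906,1540,1696.1,1109.3,1153.0,980.6,17655.5,937.5
CHEMBL590808,1600,1662.5,1799.1,1709.4,51882.2,48813.2,48302.3
CHEMBL1170748,1700,1974.2,1940.4,1652.8,3251.4,2734.9,407.6
CHEMBL253541,1800,43066.9,42831.1,79622.8,1255.9,1099.1,15566.3
CHEMBL176554,1900,572.3,7226.3,9126.2,1096.1,3352.6,3926.3
CHEMBL377597,2000,938.5,6719.7,5644.6,50.4,116.9,105.4
CHEMBL1170749,2200,10874.0,30873.8,3995.6,5835.1,25044.3,1090.5
CHEMBL590336,2200,507.8,594.0,516.4,568.9,544.3,521.1
CHEMBL590807,2200,52944.6,70480.3,52639.4,44898.4,49196.7,36195.2
CHEMBL600868,2200,1342.8,1603.8,1312.9,7373.6,5797.7,4864.3
CHEMBL398759,2300,666.0,2847.2,1010.2,447.2,924.3,309.0
CHEMBL604459,2300,1176.9,2299.2,1369.3,614.2,877.8,682.5
CHEMBL179383,2400,15724.9,14621.7,14257.4,4508.5,4132.8,4023.9
CHEMBL592489,2400,469.2,494.6,486.9,204.7,240.5,208.4
CHEMBL425904,2800,605.0,651.0,534.9,478.1,451.9,488.6
CHEMBL150894,3000,537.8,844.9,797.6,186.8,600.2,289.0
CHEMBL590793,3000,475.4,2480.4,1251.5,192.0,251.7,205.4
CHEMBL600865,4400,796.9,2072.3,1223.3,198.1,261.3,228.1
CHEMBL249253,5000,659.8,503.6,499.5,406.6,227.9,309.5
CHEMBL587506,5200,1050.8,1293.3,1083.2,2201.3,2162.7,1656.0
CHEMBL204930,5800,755.5,1260.7,1105.5,47881.6,47912.3,47868.0
CHEMBL554900,5900,6722.8,580526.0,807309.0,745.4,428.2,47897.1
CHEMBL176276,6000,3360.2,8955.9,8476.6,2075.6,2054.0,1970.7
CHEMBL589091,6100,1319.5,1308.4,1172.0,579.2,603.1,600.9
CHEMBL559781,7400,91783.7,822917.0,1230010.0,414.5,6865.5,47911.9
CHEMBL249252,8000,100671.0,38586.8,31129.8,590.5,491.6,467.9
CHEMBL589089,9800,1070.7,1321.5,1002.7,38589.3,48136.2,41143.2
CHEMBL217090,10000,628.8,1010.9,1548.5,390.6,451.8,910.1
CHEMBL217092,10000,1030.2,1199.3,1908.8,379.9,625.6,707.2
CHEMBL382588,10000,1365.2,5880.3,5488.7,2560.7,3993.4,3649.4
CHEMBL590581,10000,145206.0,149922.0,108067.0,50609.5,49348.5,48302.3
CHEMBL242753,10300,1742.5,3393.1,1941.1,1202.5,2613.0,1297.3
CHEMBL398758,11000,1582.8,187965.0,1573.6,237.0,4333.9,369.0
CHEMBL399151,11000,812.1,1263.5,2069.9,334.5,1193.9,1271.6
CHEMBL395080,13450,513.5,484.0,458.6,198.5,188.9,183.3
CHEMBL1171533,15000,349604.0,296515.0,159368.0,26784.5,26699.3,45506.4
CHEMBL602729,17000,148756.0,149052.0,139465.0,224.1,324.7,229.4
CHEMBL249255,19000,182486.0,42615.8,41578.3,1698.2,616.1,683.9
CHEMBL202930,21730,12828.4,11945.6,12145.8,213.3,219.7,217.6
CHEMBL589986,22000,1167.1,1337.4,1143.5,53747.5,49155.6,49316.8
CHEMBL251471,40000,3358.9,1946.2,2075.7,512.2,423.7,3427.4
CHEMBL560056,74000,152006.0,156723.0,208466.0,223.2,208.1,190.4
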