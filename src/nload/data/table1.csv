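embayment,property_count,mean_year_built,sd_year_built,mean_travel_time_yr,sd_travel_time_yr,annual_max_load_kg
Allen Harbor,291,1959,40.6,26.4,32.1,2399
Barnstable Harbor,3626,1963,50.7,19.6,28.2,27754
Bass River,9532,1965,32.8,24.5,30.7,61673
Bassing Harbor-Ryders Cove,1102,1971,27.7,29.5,33.8,5501
Boat Meadow River,324,1975,36.5,31.6,33.6,1887
Bournes Pond,1041,1974,25.6,32.6,34.8,4226
Buttermilk Bay,371,1959,33.7,5.0,,2226
Centerville River,6738,1969,28.4,25.2,30.5,34161
Chase Garden Creek,3068,1970,35.7,25.2,33.4,22586
Falmouth Inner Harbor,399,1952,28.9,13.5,12.5,2097
Great Pond,4233,1972,24.2,17.8,27.1,15863
Great Sippewisset Creek,475,1973,37.8,16.5,20.3,2881
Green Pond,1316,1973,21.5,29.2,34.7,5492
Herring River,3999,1967,40.4,30.5,34.8,25525
Herring River (Eastham),354,1979,22.9,9.2,12.6,2068
Lewis Bay,6131,1964,25.4,19.9,25.5,36369
Little Namskaket Creek,250,1960,49.4,47.4,38.5,15905
Little Pond,1180,1964,19.0,14.1,20.2,4980
Little Sippewisset Marsh,262,1976,21.5,8.4,5.3,1309
Long Pond,1254,1970,9.5,42.8,39.8,7768
Megansett Harbor,722,1956,39.5,5.0,,3845
Muddy Creek,1157,1976,30.5,18.4,25.4,7028
Namskaket Creek,590,1978,29.2,16.6,16.0,2966
Oyster Pond,153,1964,28.1,21.9,25.9,1010
Pamet River,546,1948,63.3,17.4,23.1,2960
Parkers River,3134,1968,14.2,30.3,34.9,19952
Phinneys Harbor-Back River,1162,1960,40.6,6.1,4.1,5505
Pleasant Bay,4661,1966,42.3,32.6,35.4,30781
Pocasset Harbor,1571,1954,38.7,5.4,1.9,6982
Pocasset River,709,1961,34.5,5.1,1.1,3159
Popponesset Bay,6496,1983,21.5,22.6,30.3,24398
Provincetown Harbor,1405,1935,60.8,7.2,10.3,9191
Quissett Harbor,140,1938,52.3,41.7,38.5,1012
Quivett Creek,554,1969,46.3,32.1,34.0,3517
Rands Canal Fiddler Cove,498,1965,44.8,7.0,5.8,3429
Red River,1266,1971,26.0,18.3,26.4,6341
Rock Harbor,342,1941,58.7,23.8,27.3,13772
Rushy Marsh Pond,6,1973,27.2,6.7,4.1,63
Salt Pond,235,1953,41.4,20.0,18.3,1389
Sandwich Harbor,1871,1954,57.9,19.8,29.2,14575
Saquatucket Harbor,1086,1962,45.6,36.2,34.6,8045
Scorton Harbor,2287,1978,28.6,25.0,28.9,15249
Sesuit Harbor,1376,1972,36.0,27.9,33.2,9363
Stage Harbor,1389,1959,45.1,33.8,37.0,6796
Sulfur Springs-Bucks Creek,1030,1970,30.7,17.4,24.3,4640
Swan Pond River,2052,1964,24.4,31.3,35.7,11721
Taylors Pond-Mill Creek,685,1961,44.0,11.7,11.8,2913
Three Bay,6795,1975,32.5,22.3,30.1,33954
Town Cove-Nauset Marsh,2806,1963,43.1,26.4,31.8,19803
Waquoit Bay,5897,1980,23.0,23.0,31.8,28779
Wellfleet Harbor,3882,1964,47.3,21.2,27.1,25333
West Falmouth Harbor,705,1960,49.8,22.8,33.6,3945
Wild Harbor,1271,1976,29.0,13.3,15.4,7021
Wychmere Harbor,129,1916,64.1,7.3,4.2,1042
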