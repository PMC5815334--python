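covariate,level,statpop_alive,statpop_died,se_alive,se_died
age,"[15, 20)",453418,125,19890,6
age,"[20, 25)",497932,195,20467,10
age,"[25, 30)",535327,179,23935,3
age,"[30, 35)",542177,250,26445,8
age,"[35, 40)",562531,330,27456,11
age,"[40, 45)",636715,662,30282,21
age,"[45, 50)",651880,1087,31172,42
age,"[50, 55)",565305,1525,26896,52
age,"[55, 60)",484779,2048,23522,70
age,"[60, 65)",456872,3110,22204,122
age,"[65, 70)",393251,4259,19730,180
age,"[70, 75)",298540,5082,15000,163
age,"[75, 80)",248981,7565,12520,300
age,"[80, 85)",184460,10711,9040,323
age,">=85",155656,24411,6549,660
gender,Men,3270394,29804,151684,1099
gender,Women,3397430,31735,163424,872
nationality,Swiss,5147117,56418,249184,1779
nationality,EEA,989417,4309,45200,172
nationality,Other Europe,317233,538,12503,14
nationality,Other World,214057,274,8221,6
civil_status,Single,2224776,7455,101868,189
civil_status,Married,3449816,24937,166452,999
civil_status,Widowed,387352,23109,17942,592
civil_status,Other,605880,6038,28846,191
region,City of Zurich,334727,3438,39120,286
region,Remainder of canton Zurich,837660,6681,24948,119
region,City of Bern,113968,1331,13139,111
region,Bernese Jura,43374,518,2899,22
region,Remainder of canton Bern,689868,7072,21957,130
region,Lucerne,318109,2750,19208,96
region,Uri,29375,315,976,5
region,Schwyz,122585,1053,3589,19
region,Obwalden,29675,249,828,4
region,Nidwalden,34471,270,1039,6
region,Glarus,32785,364,914,7
region,Zug,94883,704,5205,23
region,Fribourg,228838,1948,6570,39
region,Solothurn,216854,2161,6598,54
region,Basel-Stadt,162021,2026,5113,26
region,Basel-Landschaft,234029,2195,7366,44
region,Schaffhausen,65688,713,2001,18
region,Appenzell Ausserrhoden,43940,444,1382,15
region,Appenzell Innerrhoden,12738,135,381,2
region,St. Gallen,405528,3657,12174,57
region,Graubuenden,174072,1615,5070,32
region,Aargau,513802,4350,30046,164
region,Thurgau,209311,1881,12137,73
region,Ticino,284417,2856,17343,123
region,Vaud,603119,5165,34465,232
region,Valais,265481,2492,7112,49
region,Neuchatel,143272,1501,9295,73
region,Geneva,365634,3013,20510,112
region,Jura,57600,642,3723,30
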