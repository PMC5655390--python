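station_id,name,easting,northing,n_samples,fabric,pm25_mean,pm25_se,pm25_min,pm25_max,pm10_mean,pm10_se,pm10_min,pm10_max,ratio
1,Vasee Hospital,560739,4011590,4,Boulevard,67.50,27.50,40,150,142.50,52.50,90,300,0.47
2,Towhid,560726,4009962,4,Town,87.50,37.50,50,200,185.00,105.00,80,500,0.47
3,Emdad,560850,4009410,9,Cross,64.44,24.15,10,250,128.80,35.17,50,400,0.50
4,Fahmideh,560894,4008890,4,Square,41.25,11.25,30,75,55.00,15.00,40,100,0.75
5,Laleh,561250,4008838,4,Square,62.50,22.50,40,130,82.50,22.50,60,150,0.75
6,Motahari,561295,4008542,4,Avenue,62.50,12.50,50,100,122.50,2.50,120,130,0.51
7,Shariati,562215,4008214,6,Square,43.33,11.45,30,100,76.66,16.86,40,150,0.56
8,Sherkati,562611,4008456,4,Oil station,82.50,22.50,60,150,122.50,42.50,80,250,0.67
9,Ghand va Shekar,562412,4007252,4,Cross,87.50,2.50,80,90,152.50,32.50,120,250,0.57
10,Emam Hosain Square,562552,4006760,5,Square,78.00,30.56,40,200,152.00,62.08,80,400,0.51
11,Mosalla,562885,4006661,4,Square,47.50,17.50,30,100,122.50,42.50,80,250,0.38
12,Saheb-al-Zaman,561263,4008186,4,Square,55.00,15.00,40,100,82.50,22.50,60,150,0.66
13,Emam Hosain Boulevard,562462,4006115,4,Boulevard,55.00,15.00,40,100,68.75,18.75,50,125,0.80
14,Beyhaq Oil station,561029,4005296,8,Oil station,100.00,36.30,40,350,131.25,39.02,60,400,0.76
15,Sarbedaran,558374,4006943,13,Square,107.69,34.99,20,500,234.62,107.56,30,1500,0.42
16,Shahid Beheshti,559539,4007320,6,Square,50.00,10.95,20,100,60.83,13.44,30,125,0.82
17,Enghelab,559987,4008194,7,Square,51.42,15.64,20,120,80.00,20.23,30,160,0.64
18,Kushk Square,560002,4009080,6,Square,43.33,12.01,20,100,78.33,18.87,30,150,0.55
19,Razi Avenue,561432,4009287,4,Avenue,40.00,20.00,20,100,162.50,112.50,50,500,0.24
20,Razi Square,562627,4009071,4,Square,47.50,17.50,30,100,122.50,42.50,80,250,0.38
21,Azad University Street,562234,4008640,4,Street,47.50,17.50,30,100,82.50,22.50,60,150,0.57
22,Dadgostari,561260,4007744,7,Cross,55.71,15.86,30,150,92.85,18.47,60,200,0.60
23,Hakim,560765,4007752,4,Square,40.00,20.00,20,100,112.50,62.50,50,300,0.35
24,Kushk Cross,560414,4007744,5,Cross,44.00,14.35,20,100,62.00,22.22,30,150,0.70
25,Bazar-e-Ruz,560094,4007333,4,Square,55.00,15.00,40,100,82.50,22.50,60,150,0.66
26,Darvaz-e-Araq,560411,4007246,4,Square,55.00,15.00,40,100,115.00,5.00,110,130,0.47
27,Resalat Avenue,560460,4006490,4,Avenue,47.50,17.50,30,100,82.50,22.50,60,150,0.57
28,Asrar,560754,4006995,8,Square,51.00,11.54,10,100,90.00,21.21,20,200,0.56
29,Beyhaq Cross,560776,4007194,10,Cross,75.40,15.21,30,200,124.00,31.83,50,400,0.60
30,Post va Telegraph,561452,4007085,9,Square,66.00,17.55,20,200,114.44,32.23,30,350,0.57
31,Kargar,561754,4007056,4,Square,62.50,12.50,50,100,82.50,22.50,60,150,0.75
32,Abumoslem,561876,4007518,4,Avenue,27.50,7.50,20,50,82.50,22.50,60,150,0.33
33,Jalal al Ahmad,560471,4008148,4,Square,27.50,7.50,20,50,82.50,22.50,60,150,0.33
34,Tabas,560825,4008187,11,Square,52.72,7.98,30,100,98.18,16.22,60,250,0.53
35,Hoveyze,559901,4007964,4,Avenue,27.50,7.50,20,50,82.50,22.50,60,150,0.33
36,Mashhad Highway,560399,4005465,4,Highway,27.50,7.50,20,50,82.50,22.50,60,150,0.33
37,Resalat Oil station,560248,4006154,4,Oil station,27.50,7.50,20,50,82.50,22.50,60,150,0.33
38,Modares,561406,4006913,4,Boulevard,27.50,7.50,20,50,82.50,22.50,60,150,0.33
39,Emam Ali,560440,4008047,4,Oil station,27.50,7.50,20,50,82.50,22.50,60,150,0.33
40,University Boulevard,560610,4010673,4,Boulevard,27.50,7.50,20,50,82.50,22.50,60,150,0.33
41,North Beltway,562625,4010264,4,Boulevard,27.50,7.50,20,50,82.50,22.50,60,150,0.33
42,Azad Medical University,562772,4009294,4,Street,27.50,7.50,20,50,82.50,22.50,60,150,0.33
43,Ghuchan Road,563129,4008739,4,Road (first of),100.00,40.00,60,220,200.00,100.00,100,500,0.50
44,Mashhad Road,563085,4005747,4,Road (first of),27.50,7.50,20,50,122.50,42.50,80,250,0.22
45,Vegetable Field,560004,4005722,4,High Way,67.50,27.50,40,150,122.50,42.50,80,250,0.55
46,Beyhaq Avenue,559805,4007366,4,Avenue,27.50,7.50,20,50,82.50,22.50,60,150,0.33
47,Police Sabzevar-Tehran,556256,4007013,4,Road (first of),47.50,17.50,30,100,162.50,112.50,50,500,0.29
48,Esfarayen,558544,4009290,4,Road (first of),67.50,27.50,40,150,102.50,32.50,150,200,0.65
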