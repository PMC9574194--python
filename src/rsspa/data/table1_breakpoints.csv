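iaqi,SO2,NO2,PM10,CO,O3,PM2.5
0,0,0,0,0,0,0
50,50,40,50,2,100,35
100,150,80,150,4,160,75
150,475,180,250,14,215,115
200,800,280,350,24,265,150
300,1600,565,420,36,800,250
400,2100,750,500,48,,350
500,2620,940,600,60,,500
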