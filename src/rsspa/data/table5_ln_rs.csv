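year,k,lnk,PM2.5,PM10,O3,NO2,CO,SO2,AQI
2014,2,0.69,0,0,0,0,0,0,0
2015,3,1.10,0.25,0.23,0.35,0.26,0.34,0.25,0.28
2016,4,1.39,0.63,0.61,0.59,0.51,0.46,0.57,0.56
2017,5,1.61,0.83,0.82,0.81,0.49,0.69,0.78,0.74
2018,6,1.79,0.95,0.95,1.03,0.63,0.90,0.92,0.90
2019,7,1.95,1.08,1.08,1.18,1.02,1.11,1.07,1.09
2020,8,2.08,1.20,1.19,1.20,1.21,1.26,1.20,1.21
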