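year,pollutant,a,b1,b2,b3,c
2013,PM2.5,0,0.175,0.825,0,0
2013,PM10,0,0.6,0.4,0,0
2013,O3,0,0.582,0.418,0,0
2013,NO2,0.725,0.275,0,0,0
2013,CO,0,0.97,0.03,0,0
2013,SO2,0.76,0.24,0,0,0
2014,PM2.5,0,0.5,0.5,0,0
2014,PM10,0,0.85,0.15,0,0
2014,O3,0.017,0.983,0,0,0
2014,NO2,0.8,0.2,0,0,0
2014,CO,0.2,0.8,0,0,0
2014,SO2,0.95,0.05,0,0,0
2015,PM2.5,0,0.95,0.05,0,0
2015,PM10,0.14,0.86,0,0,0
2015,O3,0,1,0,0,0
2015,NO2,0.85,0.15,0,0,0
2015,CO,0.15,0.85,0,0,0
2015,SO2,1,0,0,0,0
2016,PM2.5,0.125,0.875,0,0,0
2016,PM10,0.27,0.73,0,0,0
2016,O3,0,0.8,0.2,0,0
2016,NO2,0.775,0.225,0,0,0
2016,CO,0.35,0.65,0,0,0
2016,SO2,1,0,0,0,0
2017,PM2.5,0.25,0.75,0,0,0
2017,PM10,0.33,0.67,0,0,0
2017,O3,0,0.4,0.6,0,0
2017,NO2,0.825,0.175,0,0,0
2017,CO,0.55,0.45,0,0,0
2017,SO2,1,0,0,0,0
2018,PM2.5,0.25,0.75,0,0,0
2018,PM10,0.46,0.54,0,0,0
2018,O3,0,0.4,0.6,0,0
2018,NO2,0.925,0.075,0,0,0
2018,CO,0.85,0.15,0,0,0
2018,SO2,1,0,0,0,0
2019,PM2.5,0.25,0.75,0,0,0
2019,PM10,0.57,0.43,0,0,0
2019,O3,0,0.455,0.545,0,0
2019,NO2,1,0,0,0,0
2019,CO,0.95,0.05,0,0,0
2019,SO2,1,0,0,0,0
2020,PM2.5,0.25,0.75,0,0,0
2020,PM10,0.71,0.29,0,0,0
2020,O3,0,0.745,0.255,0,0
2020,NO2,1,0,0,0,0
2020,CO,1,0,0,0,0
2020,SO2,1,0,0,0,0
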