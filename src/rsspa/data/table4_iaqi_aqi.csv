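year,PM2.5,PM10,O3,NO2,CO,SO2,AQI
2013,141.25,120.00,120.91,77.50,101.50,74.00,141.25
2014,125.00,107.50,148.33,70.00,130.00,55.00,148.33
2015,102.50,136.00,150.00,65.00,135.00,41.00,150.00
2016,137.50,123.00,110.00,72.50,115.00,34.00,137.50
2017,125.00,117.00,130.00,67.50,95.00,27.00,130.00
2018,102.50,104.00,130.00,57.50,65.00,20.00,130.00
2019,88.00,93.00,127.27,48.75,55.00,15.00,127.27
2020,74.50,79.00,112.73,42.50,45.00,13.00,112.73
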