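metric,PM2.5,PM10,O3,NO2,CO,SO2,AQI
hurst,0.8905,0.8946,0.9146,0.803,0.8965,0.8847,0.8826
r_squared,0.9904,0.9878,0.9935,0.8973,0.975,0.9939,0.9949
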