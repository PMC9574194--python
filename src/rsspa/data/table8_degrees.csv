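year,a,b1,b2,trend_second,degree,trend_fourth
2013,0.2475,0.474,0.325,Decrease,0.485,Improve
2014,0.328,0.564,0.108,Improve,0.610,Improve
2015,0.357,0.627,0.008,Improve,0.671,Improve
2016,0.42,0.545,0.033,Improve,0.693,Improve
2017,0.4925,0.4075,0.1,Improve,0.696,Improve
2018,0.581,0.319,0.1,Improve,0.741,Improve
2019,0.628,0.281,0.091,Improve,0.769,Improve
2020,0.66,0.2975,0.0425,Improve,0.809,Improve
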