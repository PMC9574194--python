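lower,upper,level,category,color
0,50,1,excellent,green
51,100,2,good,yellow
101,150,3,slightly-pollution,orange
151,200,4,moderate-pollution,red
201,300,5,severely-pollution,purple
301,,6,seriously-pollution,maroon
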