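lower,upper,grade,level
-1,-0.6,I,unsafe
-0.6,-0.2,II,less safe
-0.2,0.2,III,critical safe
0.2,0.6,IV,relatively safe
0.6,1,V,safe
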