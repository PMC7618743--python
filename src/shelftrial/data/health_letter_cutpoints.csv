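category,letter,min_raw,max_raw
general,A,-15,-1
general,B,0,2
general,C,3,10
general,D,11,18
general,E,19,40
beverage,B,-15,1
beverage,C,2,5
beverage,D,6,9
beverage,E,10,40
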