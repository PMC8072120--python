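pollination_type,random,vascular,none
bat,1,0,0
bee,3,5,1
hummingbird,0,15,5
moth,0,0,1
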