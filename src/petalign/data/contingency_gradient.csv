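pollination_type,distal,proximal,none
bat,0,0,1
bee,2,4,3
hummingbird,18,0,2
moth,0,0,1
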