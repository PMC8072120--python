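species,count,pollination_type,accession
Sinningia aggregata,26,hummingbird,K039091;K039092;K039093;K039297
Sinningia barbata,3,bee,K039105
Sinningia brasiliensis,17,bat,K023999;K024028;K024030;K024040;K024074
Sinningia bullata,42,to_be_determined,K023430;K023431;K023443;K023448;K037111
Sinningia concinna,10,bee,K039117
Sinningia conspicua,5,bee,K039121
Sinningia defoliata,3,hummingbird,K023265;K039125
Sinningia eumorpha,36,bee,K039133
Sinningia gesneriifolia,9,to_be_determined,K039220;K039221
Sinningia guttata,3,bee,K039134
Sinningia harleyi,7,hummingbird,K039135
Sinningia helioana,6,to_be_determined,K039222
Sinningia hirsuta,4,bee,K039136
Sinningia incarnata,3,hummingbird,K039137
Sinningia insularis,28,hummingbird,K039142;K039145
Sinningia kautskyi,9,bee,K039146;K039147
Sinningia leopoldii,9,hummingbird,K039148;K039150
Sinningia leucotricha,6,hummingbird,K039157
Sinningia lineata,43,hummingbird,K039159;K039162;K039163
Sinningia macropoda,19,hummingbird,K023363;K023405;K023413;K039164
Sinningia macrostachya,9,hummingbird,K023944;K039165
Sinningia magnifica,4,hummingbird,K039166
Sinningia mauroana,10,hummingbird,K024149;K024154;K024169
Sinningia minima,4,to_be_determined,S82P101
Sinningia nordestina,29,hummingbird,K039168
Sinningia piresiana,9,hummingbird,K023312;K023333
Sinningia reitzii,15,hummingbird,K039173
Sinningia richii,5,bee,K039176
Sinningia sceptrum,10,hummingbird,K039178;K039182
Sinningia sellovii,21,hummingbird,K023224;K039184;K039185
Sinningia speciosa,11,bee,K039190
Sinningia tubiflora,4,moth,K039191
Sinningia warmingii,14,hummingbird,K039206;K039207
Vanhouttea hilariana,21,hummingbird,K039218
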