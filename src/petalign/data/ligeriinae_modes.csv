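species,variegated,gradient
Sinningia aggregata,vascular,distal
Sinningia barbata,none,none
Sinningia brasiliensis,random,none
Sinningia bullata,vascular,distal
Sinningia concinna,vascular,distal
Sinningia conspicua,vascular,none
Sinningia defoliata,vascular,distal
Sinningia eumorpha,vascular,proximal
Sinningia gesneriifolia,random,proximal
Sinningia guttata,random,proximal
Sinningia harleyi,vascular,distal
Sinningia helioana,none,distal
Sinningia hirsuta,random,proximal
Sinningia incarnata,none,distal
Sinningia insularis,none,distal
Sinningia kautskyi,vascular,proximal
Sinningia leopoldii,vascular,distal
Sinningia leucotricha,vascular,distal
Sinningia lineata,vascular,distal
Sinningia macropoda,vascular,distal
Sinningia macrostachya,vascular,none
Sinningia magnifica,vascular,distal
Sinningia mauroana,vascular,distal
Sinningia minima,vascular,distal
Sinningia nordestina,vascular,none
Sinningia piresiana,vascular,distal
Sinningia reitzii,vascular,distal
Sinningia richii,vascular,none
Sinningia sceptrum,none,distal
Sinningia sellovii,vascular,distal
Sinningia speciosa,random,distal
Sinningia tubiflora,none,none
Sinningia warmingii,none,distal
Vanhouttea hilariana,vascular,distal
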