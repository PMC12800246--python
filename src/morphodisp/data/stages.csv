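name,start_ma,end_ma
Ludfordian,425.6,423.0
Pridoli,423.0,419.2
Lochkovian,419.2,410.8
Pragian,410.8,407.6
Emsian,407.6,393.3
Eifelian,393.3,387.7
Givetian,387.7,382.7
Frasnian,382.7,372.2
Famennian,372.2,358.9
Tournaisian,358.9,346.7
Visean,346.7,330.9
Serpukhovian,330.9,323.2
Bashkirian,323.2,315.2
Moscovian,315.2,307.0
Kasimovian,307.0,303.7
Gzhelian,303.7,298.9
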