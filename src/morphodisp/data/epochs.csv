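name,start_ma,end_ma
Ludlow,425.6,423.0
Pridoli,423.0,419.2
Lower Devonian,419.2,393.3
Middle Devonian,393.3,382.7
Upper Devonian,382.7,358.9
Mississippian,358.9,323.2
Pennsylvanian,323.2,298.9
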