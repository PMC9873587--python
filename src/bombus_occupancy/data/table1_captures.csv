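species,trap_unburned,trap_burned,net_burned
bifarius,29,101,47
mixtus,21,45,12
flavifrons,20,26,7
melanopygus,5,19,5
sitkensis,5,4,0
rufocinctus,0,7,11
insularis,1,2,9
jonellus,0,2,0
flavidus,0,2,10
kirbiellus,0,1,0
terricola,0,0,1
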