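species,stanza_index,group,start_age_months,z,vbk,leading
Antarctic krill,0,Small krill,0,0.8,0.440,0
Antarctic krill,1,Large krill,24,0.8,0.440,1
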