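entry,printed,used,justification
Other euphausiids biomass,148000.00,14800.0,Order-of-magnitude transcription error; the large-phytoplankton biomass solved from EE=0.5 matches the printed 13712.00 only with the corrected value.
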