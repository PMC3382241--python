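# Kappa light-chain locus: V 12-spacer, J 23-spacer, no D segments.
locus: IGK
v_spacer_class: 12-type
j_spacer_class: 23-type
has_d_segments: false
detect_switch_regions: false
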