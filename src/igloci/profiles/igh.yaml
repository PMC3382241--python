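# Heavy-chain locus: V segments carry 23-spacer RSSs, D segments are
# flanked by 12-spacer RSSs, J segments carry upstream 23-spacer RSSs,
# and switch repeat arrays precede the constant-region genes.
locus: IGH
v_spacer_class: 23-type
j_spacer_class: 23-type
has_d_segments: true
detect_switch_regions: true
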