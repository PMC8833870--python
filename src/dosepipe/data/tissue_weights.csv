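region,weight
red_marrow,0.12
bone_surfaces,0.01
bladder_wall,0.04
kidneys,0.0092
other_tissue,0.12
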