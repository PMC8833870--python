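region,mass_g
red_marrow,1500
kidneys,299
bone_surfaces,120
bladder_wall,50
other_tissue,60000
cortical_surface,4400
trabecular_surface,1100
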