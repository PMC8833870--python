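source,target,s_value_Gy_per_MBq_h
cortical_surface,red_marrow,1.35e-6
trabecular_surface,red_marrow,6.5e-6
red_marrow,red_marrow,2.3e-4
kidneys,red_marrow,2.0e-7
bladder_content,red_marrow,1.0e-7
remainder,red_marrow,2.0e-6
cortical_surface,kidneys,1.0e-7
trabecular_surface,kidneys,1.0e-7
red_marrow,kidneys,2.0e-7
kidneys,kidneys,2.64e-4
bladder_content,kidneys,2.0e-7
remainder,kidneys,1.5e-6
cortical_surface,bone_surfaces,1.3e-5
trabecular_surface,bone_surfaces,1.3e-5
red_marrow,bone_surfaces,3.0e-6
kidneys,bone_surfaces,1.0e-7
bladder_content,bone_surfaces,1.0e-7
remainder,bone_surfaces,1.0e-6
cortical_surface,bladder_wall,1.0e-7
trabecular_surface,bladder_wall,1.0e-7
red_marrow,bladder_wall,1.0e-7
kidneys,bladder_wall,1.0e-7
bladder_content,bladder_wall,1.5e-4
remainder,bladder_wall,1.2e-6
cortical_surface,other_tissue,2.0e-7
trabecular_surface,other_tissue,2.0e-7
red_marrow,other_tissue,2.0e-7
kidneys,other_tissue,2.0e-7
bladder_content,other_tissue,2.0e-7
remainder,other_tissue,1.4e-6
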