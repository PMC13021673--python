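roi_id,s01,s02,s03,s04,s05,s06,s07,s08,s09,s10
frontal_cortex_b,-1,0,0,0,-1,0,0,0,0,0
temporal_cortex_b,-1,0,0,0,0,0,0,0,0,0
cingulate_gyrus_b,-1,0,0,0,0,0,0,0,0,0
cerebellum_b,-1,0,0,0,0,0,0,0,0,0
dacc_r,0,1,0,0,0,0,0,0,0,0
dpcc_r,0,1,0,0,0,0,0,0,0,0
precuneus_b,0,0,-1,0,-1,0,0,0,0,-1
med_ofc_b,0,0,-1,0,0,0,0,0,0,0
hippocampus_b,0,0,-1,0,0,0,0,-1,0,-1
ant_parietal_b,0,0,0,-1,0,0,0,0,0,0
temporal_operculum_b,0,0,0,-1,0,0,0,0,0,0
sup_frontal_r,0,0,0,-1,0,0,-1,0,0,0
mid_frontal_r,0,0,0,-1,0,-1,-1,0,0,0
thalamus_l,0,0,0,-1,0,0,0,0,0,0
racc_wm_b,0,0,0,0,-1,0,0,0,0,0
isthmus_cingulate_b,0,0,0,0,-1,0,0,0,0,0
cuneus_b,0,0,0,0,-1,0,0,0,0,0
frontal_gyrus_l,0,0,0,0,0,-1,0,0,0,0
med_temporal_l,0,0,0,0,0,-1,0,0,0,0
parietal_cortex_l,0,0,0,0,0,-1,0,0,0,0
precentral_r,0,0,0,0,0,0,-1,0,0,0
ant_insula_r,0,0,0,0,0,0,-1,0,0,0
rolandic_operculum_r,0,0,0,0,0,0,-1,0,0,0
sup_temporal_pole_r,0,0,0,0,0,0,-1,0,0,0
thalamus_b,-1,0,0,0,0,0,0,-1,0,-1
pontine_reticular_b,0,0,0,0,0,0,0,0,-1,0
slf_r,0,0,0,0,0,0,-1,0,0,0
frontal_aslant_r,0,0,0,0,0,0,-1,0,0,0
frontopontine_r,0,0,0,0,0,0,-1,0,0,0
arcuate_r,0,0,0,0,0,0,-1,0,0,0
external_capsule_r,0,0,0,0,0,0,-1,0,0,0
cst_r,0,0,0,0,0,0,-1,0,0,0
post_cingulate_b,0,0,0,0,0,0,0,0,0,-1
mid_cingulate_b,0,0,0,0,0,0,0,0,0,-1
corpus_callosum_b,0,0,0,0,0,0,0,0,0,-1
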