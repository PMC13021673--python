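roi_id	study_id	source_sentence_tag	confidence
frontal_cortex_b	s01	s01_frontal_temporal_cingulate	NARRATIVE
temporal_cortex_b	s01	s01_frontal_temporal_cingulate	NARRATIVE
cingulate_gyrus_b	s01	s01_frontal_temporal_cingulate	NARRATIVE
thalamus_b	s01	s01_subcortical_gm_consolidated_to_thalamus	NARRATIVE
cerebellum_b	s01	s01_cerebellum	NARRATIVE
dacc_r	s02	s02_dorsal_cingulate_increases	NARRATIVE
dpcc_r	s02	s02_dorsal_cingulate_increases	NARRATIVE
precuneus_b	s03	s03_precuneus_mofc	NARRATIVE
med_ofc_b	s03	s03_precuneus_mofc	NARRATIVE
hippocampus_b	s03	s03_hippocampal_atrophy	NARRATIVE
ant_parietal_b	s04	s04_parietal_opercular	NARRATIVE
temporal_operculum_b	s04	s04_parietal_opercular	NARRATIVE
sup_frontal_r	s04	s04_frontal_gyri	NARRATIVE
mid_frontal_r	s04	s04_frontal_gyri	NARRATIVE
thalamus_l	s04	s04_left_thalamus	NARRATIVE
racc_wm_b	s05	s05_longitudinal_first_year	NARRATIVE
isthmus_cingulate_b	s05	s05_longitudinal_first_year	NARRATIVE
precuneus_b	s05	s05_longitudinal_first_year	NARRATIVE
cuneus_b	s05	s05_longitudinal_first_year	NARRATIVE
frontal_cortex_b	s05	s05_distributed_frontal	NARRATIVE
frontal_gyrus_l	s06	s06_gm_proportion	NARRATIVE
mid_frontal_r	s06	s06_gm_proportion	NARRATIVE
med_temporal_l	s06	s06_gm_proportion	NARRATIVE
parietal_cortex_l	s06	s06_gm_proportion	NARRATIVE
sup_frontal_r	s07	s07_gm_probability	NARRATIVE
mid_frontal_r	s07	s07_gm_probability	NARRATIVE
precentral_r	s07	s07_gm_probability	NARRATIVE
ant_insula_r	s07	s07_gm_probability	NARRATIVE
rolandic_operculum_r	s07	s07_gm_probability	NARRATIVE
sup_temporal_pole_r	s07	s07_gm_probability	NARRATIVE
slf_r	s07	s07_wm_probability_tracts	NARRATIVE
frontal_aslant_r	s07	s07_wm_probability_tracts	NARRATIVE
frontopontine_r	s07	s07_wm_probability_tracts	NARRATIVE
arcuate_r	s07	s07_wm_probability_tracts	NARRATIVE
external_capsule_r	s07	s07_wm_probability_tracts	NARRATIVE
cst_r	s07	s07_wm_probability_tracts	NARRATIVE
thalamus_b	s08	s08_progressive_thalamus_hippocampus	NARRATIVE
hippocampus_b	s08	s08_progressive_thalamus_hippocampus	NARRATIVE
pontine_reticular_b	s09	s09_tbm_pontine	NARRATIVE
post_cingulate_b	s10	s10_reconstructed_midline	RECONSTRUCTED_LOW_CONFIDENCE
mid_cingulate_b	s10	s10_reconstructed_midline	RECONSTRUCTED_LOW_CONFIDENCE
thalamus_b	s10	s10_reconstructed_midline	RECONSTRUCTED_LOW_CONFIDENCE
hippocampus_b	s10	s10_reconstructed_midline	RECONSTRUCTED_LOW_CONFIDENCE
precuneus_b	s10	s10_reconstructed_midline	RECONSTRUCTED_LOW_CONFIDENCE
corpus_callosum_b	s10	s10_reconstructed_callosal	RECONSTRUCTED_LOW_CONFIDENCE
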