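roi_id	label	hemisphere	tissue	networks
frontal_cortex_b	Frontal cortex (distributed)	B	GM	FPN
temporal_cortex_b	Temporal cortex	B	GM	LIM
cingulate_gyrus_b	Cingulate gyrus	B	GM	DMN;LIM
cerebellum_b	Cerebellar cortex	B	GM	BSC
dacc_r	Dorsal anterior cingulate cortex	R	GM	SAL;DMN
dpcc_r	Dorsal posterior cingulate cortex	R	GM	DMN
precuneus_b	Precuneus	B	GM	DMN
med_ofc_b	Medial orbitofrontal cortex	B	GM	DMN;LIM
hippocampus_b	Hippocampus	B	GM	LIM;DMN
ant_parietal_b	Anterior parietal cortex	B	GM	SMN
temporal_operculum_b	Temporal operculum	B	GM	SAL
sup_frontal_r	Superior frontal gyrus	R	GM	FPN
mid_frontal_r	Middle frontal gyrus	R	GM	FPN
thalamus_l	Thalamus (left)	L	GM	LIM
racc_wm_b	Rostral anterior cingulate white matter	B	WM	SAL;DMN
isthmus_cingulate_b	Isthmus of the cingulate	B	GM	DMN
cuneus_b	Cuneus	B	GM	SMN
frontal_gyrus_l	Frontal gyrus (left)	L	GM	FPN
med_temporal_l	Medial temporal lobe (left)	L	GM	LIM
parietal_cortex_l	Parietal cortex (left)	L	GM	FPN
precentral_r	Precentral gyrus	R	GM	SMN
ant_insula_r	Anterior insula	R	GM	SAL
rolandic_operculum_r	Rolandic operculum	R	GM	SMN
sup_temporal_pole_r	Superior temporal pole	R	GM	LIM
thalamus_b	Thalamus	B	GM	LIM
pontine_reticular_b	Pontine reticular formation	B	MIXED	BSC
slf_r	Superior longitudinal fasciculus	R	WM	FPN
frontal_aslant_r	Frontal aslant tract	R	WM	FPN
frontopontine_r	Frontopontine tract	R	WM	BSC
arcuate_r	Arcuate fasciculus	R	WM	FPN
external_capsule_r	External capsule	R	WM	SAL
cst_r	Corticospinal tract	R	WM	SMN
post_cingulate_b	Posterior cingulate cortex	B	GM	DMN
mid_cingulate_b	Mid cingulate cortex	B	GM	DMN;SMN
corpus_callosum_b	Corpus callosum	B	WM	CAL
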