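study_id	citation	method	design	confidence
s01	Early VBM study: GM reductions in frontal and temporal cortices, cingulate gyrus, subcortical GM and cerebellum (mixed-severity TBI)	VBM	CROSS_SECTIONAL	NARRATIVE
s02	Increased cortical volume in right dorsal anterior and posterior cingulate in mTBI with chronic post-traumatic headache	VOLUMETRY	CROSS_SECTIONAL	NARRATIVE
s03	Volume loss in precuneus and medial orbitofrontal cortex with accelerated hippocampal atrophy in recurrent mTBI	VOLUMETRY	CROSS_SECTIONAL	NARRATIVE
s04	GM reductions in anterior parietal, temporal opercular, superior and middle frontal regions and left thalamus (mTBI with/without post-traumatic headache)	VBM	CROSS_SECTIONAL	NARRATIVE
s05	Longitudinal first-year volume reductions: rostral anterior cingulate WM, isthmus cingulate, precuneus, cuneus, distributed frontal regions	VOLUMETRY	LONGITUDINAL	NARRATIVE
s06	Reduced GM proportion in left frontal, right middle frontal, left medial temporal and left parietal cortex; reductions scale with post-concussive symptom severity	GM_PROB	CROSS_SECTIONAL	NARRATIVE
s07	One-year GM/WM probability reductions: right superior/middle frontal, precentral, anterior insula, Rolandic operculum, superior temporal pole, plus six association/projection tracts	WM_PROB	LONGITUDINAL	NARRATIVE
s08	Progressive thalamic and hippocampal volume loss over the months following mTBI	VOLUMETRY	LONGITUDINAL	NARRATIVE
s09	Tensor-based morphometry volume reduction in the pontine reticular formation in chronic mTBI	TBM	CROSS_SECTIONAL	NARRATIVE
s10	Meta-analysis-derived primary VBM study without an enumerated region list; midline GM/callosal reductions reconstructed	VBM	CROSS_SECTIONAL	RECONSTRUCTED_LOW_CONFIDENCE
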