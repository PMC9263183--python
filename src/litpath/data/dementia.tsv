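# Dementia stratification dictionary (class, term).  Classes are disjoint;
# suggestive terms rescue borderline abstracts from the unrelated class.
ad_specific	alzheimer
ad_specific	alzheimers
ad_specific	app
ad_specific	abeta
ad_specific	amyloid
ad_specific	amyloid-beta
ad_specific	presenilin
ad_specific	psen1
ad_specific	psen2
ad_specific	apoe
ad_specific	tau
ad_specific	neurofibrillary tangles
ad_specific	donepezil
ad_specific	memantine
dementia_general	dementia
dementia_general	memory
dementia_general	aging
dementia_general	cognition
dementia_general	cognitive decline
dementia_general	cognitive impairment
dementia_general	mild cognitive impairment
dementia_general	elderly
dementia_general	senile
dementia_general	mci
dementia_general	caregiver
dementia_general	memory loss
dementia_general	forgetfulness
related	parkinson
related	parkinsons
related	frontotemporal
related	lewy
related	lewy body
related	vascular dementia
related	huntington
related	amyotrophic lateral sclerosis
related	als
related	synuclein
related	ftd
related	progressive supranuclear palsy
related	corticobasal
related	binswanger
unrelated	creutzfeldt
unrelated	creutzfeldt-jakob
unrelated	prion
unrelated	kuru
unrelated	scrapie
unrelated	aids dementia
unrelated	aids dementia complex
unrelated	hiv-associated dementia
unrelated	neurosyphilis
unrelated	wernicke-korsakoff
unrelated	korsakoff
unrelated	pseudodementia
unrelated	spongiform
suggestive	neurodegeneration
suggestive	neurodegenerative
suggestive	proteinopathy
suggestive	misfolding
suggestive	neuritic
suggestive	cholinergic deficit
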