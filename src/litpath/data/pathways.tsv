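# Illustrative pathway dictionaries (pathway_id, name, source, term, match_class).
# Real analyses should supply curated dictionaries; these cover a dozen
# pathways prominent in the dementia literature.
hsa05010	Alzheimer's disease	KEGG	alzheimer's disease	full
hsa05010	Alzheimer's disease	KEGG	alzheimer disease	full
hsa05010	Alzheimer's disease	KEGG	amyloid cascade	partial
hsa05010	Alzheimer's disease	KEGG	amyloid plaques	partial
hsa05012	Parkinson's disease	KEGG	parkinson's disease	full
hsa05012	Parkinson's disease	KEGG	parkinson disease	full
hsa05012	Parkinson's disease	KEGG	parkinsonism	partial
hsa05012	Parkinson's disease	KEGG	nigrostriatal	partial
R-HSA-168256	Immune system	Reactome	immune system	full
R-HSA-168256	Immune system	Reactome	immune response	partial
R-HSA-168256	Immune system	Reactome	immunity	partial
hsa04210	Apoptosis	KEGG	apoptosis	full
hsa04210	Apoptosis	KEGG	apoptotic	full
hsa04210	Apoptosis	KEGG	programmed cell death	partial
hsa04210	Apoptosis	KEGG	caspase	partial
hsa03050	Proteasome	KEGG	proteasome	full
hsa03050	Proteasome	KEGG	proteasomal	full
hsa03050	Proteasome	KEGG	ubiquitin-proteasome system	partial
hsa03050	Proteasome	KEGG	protein degradation	partial
hsa04730	Long-term depression	KEGG	long-term depression	full
hsa04730	Long-term depression	KEGG	cerebellar plasticity	partial
hsa04725	Cholinergic synapse	KEGG	cholinergic synapse	full
hsa04725	Cholinergic synapse	KEGG	cholinergic	full
hsa04725	Cholinergic synapse	KEGG	acetylcholine	partial
hsa04725	Cholinergic synapse	KEGG	nicotinic receptor	partial
hsa01100	Metabolic pathways	KEGG	metabolic pathways	full
hsa01100	Metabolic pathways	KEGG	metabolism	full
hsa01100	Metabolic pathways	KEGG	metabolic	partial
hsa04062	Chemokine signaling pathway	KEGG	chemokine signaling	full
hsa04062	Chemokine signaling pathway	KEGG	chemokine	full
hsa04062	Chemokine signaling pathway	KEGG	ccl2	partial
hsa04062	Chemokine signaling pathway	KEGG	cxcr4	partial
hsa04140	Autophagy	KEGG	autophagy	full
hsa04140	Autophagy	KEGG	autophagosome	partial
hsa04140	Autophagy	KEGG	lc3	partial
hsa04721	Synaptic vesicle cycle	KEGG	synaptic vesicle	full
hsa04721	Synaptic vesicle cycle	KEGG	exocytosis	partial
hsa04721	Synaptic vesicle cycle	KEGG	endocytosis	partial
custom-diabetes	Diabetes	custom	diabetes	full
custom-diabetes	Diabetes	custom	diabetic	full
custom-diabetes	Diabetes	custom	insulin resistance	partial
custom-diabetes	Diabetes	custom	hyperglycemia	partial
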