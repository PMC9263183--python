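# Evidence-type dictionaries (axis, side, term).
# genetic_vs_model: side_a = genetic, side_b = model
# animal_vs_human: side_a = animal, side_b = human
# invitro_vs_invivo: side_a = in vitro, side_b = in vivo
# review terms are shared across all axes and preempt every side label.
genetic_vs_model	side_a	gene
genetic_vs_model	side_a	genes
genetic_vs_model	side_a	genetic
genetic_vs_model	side_a	mutation
genetic_vs_model	side_a	mutations
genetic_vs_model	side_a	variant
genetic_vs_model	side_a	variants
genetic_vs_model	side_a	allele
genetic_vs_model	side_a	alleles
genetic_vs_model	side_a	polymorphism
genetic_vs_model	side_a	polymorphisms
genetic_vs_model	side_a	snp
genetic_vs_model	side_a	snps
genetic_vs_model	side_a	gwas
genetic_vs_model	side_a	genome-wide association
genetic_vs_model	side_a	genotype
genetic_vs_model	side_a	genotyping
genetic_vs_model	side_a	heritability
genetic_vs_model	side_a	linkage analysis
genetic_vs_model	side_a	exome
genetic_vs_model	side_a	whole-genome sequencing
genetic_vs_model	side_a	locus
genetic_vs_model	side_a	loci
genetic_vs_model	side_a	haplotype
genetic_vs_model	side_a	familial
genetic_vs_model	side_a	mutation carrier
genetic_vs_model	side_a	pedigree
genetic_vs_model	side_a	chromosome
genetic_vs_model	side_a	genomic
genetic_vs_model	side_a	mendelian
genetic_vs_model	side_b	mouse
genetic_vs_model	side_b	mice
genetic_vs_model	side_b	rat
genetic_vs_model	side_b	rats
genetic_vs_model	side_b	transgenic
genetic_vs_model	side_b	knockout
genetic_vs_model	side_b	knock-in
genetic_vs_model	side_b	murine
genetic_vs_model	side_b	animal model
genetic_vs_model	side_b	mouse model
genetic_vs_model	side_b	rat model
genetic_vs_model	side_b	cell line
genetic_vs_model	side_b	cell culture
genetic_vs_model	side_b	cultured cells
genetic_vs_model	side_b	zebrafish
genetic_vs_model	side_b	drosophila
genetic_vs_model	side_b	nematode
genetic_vs_model	side_b	primary neurons
genetic_vs_model	side_b	neuronal culture
genetic_vs_model	side_b	organoid
genetic_vs_model	side_b	organoids
genetic_vs_model	side_b	xenograft
genetic_vs_model	side_b	induced pluripotent
genetic_vs_model	side_b	ipsc
genetic_vs_model	side_b	ipscs
genetic_vs_model	side_b	cell model
genetic_vs_model	side_b	hippocampal slices
genetic_vs_model	side_b	slice culture
genetic_vs_model	side_b	hek293
genetic_vs_model	side_b	c57bl
animal_vs_human	side_a	mouse
animal_vs_human	side_a	mice
animal_vs_human	side_a	rat
animal_vs_human	side_a	rats
animal_vs_human	side_a	murine
animal_vs_human	side_a	rodent
animal_vs_human	side_a	rodents
animal_vs_human	side_a	transgenic mice
animal_vs_human	side_a	rabbit
animal_vs_human	side_a	rabbits
animal_vs_human	side_a	canine
animal_vs_human	side_a	dog
animal_vs_human	side_a	dogs
animal_vs_human	side_a	monkey
animal_vs_human	side_a	monkeys
animal_vs_human	side_a	macaque
animal_vs_human	side_a	primate
animal_vs_human	side_a	primates
animal_vs_human	side_a	zebrafish
animal_vs_human	side_a	drosophila
animal_vs_human	side_a	nematode
animal_vs_human	side_a	pig
animal_vs_human	side_a	pigs
animal_vs_human	side_a	sheep
animal_vs_human	side_a	guinea pig
animal_vs_human	side_a	hamster
animal_vs_human	side_a	mouse model
animal_vs_human	side_a	rat model
animal_vs_human	side_a	animal model
animal_vs_human	side_a	animals
animal_vs_human	side_b	patient
animal_vs_human	side_b	patients
animal_vs_human	side_b	human
animal_vs_human	side_b	humans
animal_vs_human	side_b	participants
animal_vs_human	side_b	subjects
animal_vs_human	side_b	volunteers
animal_vs_human	side_b	cohort
animal_vs_human	side_b	cohorts
animal_vs_human	side_b	clinical trial
animal_vs_human	side_b	clinical trials
animal_vs_human	side_b	randomized
animal_vs_human	side_b	placebo
animal_vs_human	side_b	double-blind
animal_vs_human	side_b	men
animal_vs_human	side_b	women
animal_vs_human	side_b	individuals
animal_vs_human	side_b	outpatients
animal_vs_human	side_b	inpatients
animal_vs_human	side_b	community-dwelling
animal_vs_human	side_b	case-control
animal_vs_human	side_b	cross-sectional
animal_vs_human	side_b	longitudinal study
animal_vs_human	side_b	epidemiological
animal_vs_human	side_b	population-based
animal_vs_human	side_b	autopsy
animal_vs_human	side_b	postmortem
animal_vs_human	side_b	brain bank
animal_vs_human	side_b	biopsy
animal_vs_human	side_b	serum samples
invitro_vs_invivo	side_a	in vitro
invitro_vs_invivo	side_a	cell culture
invitro_vs_invivo	side_a	cultured
invitro_vs_invivo	side_a	culture medium
invitro_vs_invivo	side_a	petri
invitro_vs_invivo	side_a	flask
invitro_vs_invivo	side_a	cell line
invitro_vs_invivo	side_a	cell lines
invitro_vs_invivo	side_a	hek293
invitro_vs_invivo	side_a	sh-sy5y
invitro_vs_invivo	side_a	pc12
invitro_vs_invivo	side_a	primary culture
invitro_vs_invivo	side_a	transfection
invitro_vs_invivo	side_a	transfected
invitro_vs_invivo	side_a	immunoblot
invitro_vs_invivo	side_a	western blot
invitro_vs_invivo	side_a	elisa
invitro_vs_invivo	side_a	recombinant
invitro_vs_invivo	side_a	purified protein
invitro_vs_invivo	side_a	incubation
invitro_vs_invivo	side_a	incubated
invitro_vs_invivo	side_a	microplate
invitro_vs_invivo	side_a	cuvette
invitro_vs_invivo	side_a	lysate
invitro_vs_invivo	side_a	lysates
invitro_vs_invivo	side_a	supernatant
invitro_vs_invivo	side_a	monolayer
invitro_vs_invivo	side_a	passage number
invitro_vs_invivo	side_a	enzymatic assay
invitro_vs_invivo	side_a	binding assay
invitro_vs_invivo	side_b	in vivo
invitro_vs_invivo	side_b	intraperitoneal
invitro_vs_invivo	side_b	intravenous
invitro_vs_invivo	side_b	oral administration
invitro_vs_invivo	side_b	gavage
invitro_vs_invivo	side_b	behavioral testing
invitro_vs_invivo	side_b	morris water maze
invitro_vs_invivo	side_b	open field
invitro_vs_invivo	side_b	rotarod
invitro_vs_invivo	side_b	body weight
invitro_vs_invivo	side_b	plasma levels
invitro_vs_invivo	side_b	cerebrospinal fluid
invitro_vs_invivo	side_b	csf
invitro_vs_invivo	side_b	perfusion
invitro_vs_invivo	side_b	sacrificed
invitro_vs_invivo	side_b	implanted
invitro_vs_invivo	side_b	telemetry
invitro_vs_invivo	side_b	blood-brain barrier
invitro_vs_invivo	side_b	microdialysis
invitro_vs_invivo	side_b	pet imaging
invitro_vs_invivo	side_b	mri
invitro_vs_invivo	side_b	histology
invitro_vs_invivo	side_b	immunohistochemistry
invitro_vs_invivo	side_b	brain sections
invitro_vs_invivo	side_b	injected
invitro_vs_invivo	side_b	dosing
invitro_vs_invivo	side_b	pharmacokinetics
invitro_vs_invivo	side_b	locomotor
invitro_vs_invivo	side_b	treatment group
invitro_vs_invivo	side_b	survival analysis
shared	review	review
shared	review	systematic review
shared	review	meta-analysis
shared	review	literature review
shared	review	this review
shared	review	narrative review
shared	review	we review
shared	review	overview of the literature
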