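# Negative-finding phrases and exclusion-criterion phrases (kind, phrase).
negative	no significant association
negative	no association
negative	not associated with
negative	did not differ
negative	no evidence of
negative	failed to show
negative	showed no effect
negative	no significant difference
negative	negative findings
negative	null result
exclusion	dementia were excluded
exclusion	excluded patients with dementia
exclusion	patients with dementia were excluded
exclusion	subjects with dementia were excluded
exclusion	excluded subjects with dementia
exclusion	without dementia
exclusion	free of dementia
exclusion	no history of dementia
exclusion	dementia as an exclusion criterion
exclusion	exclusion criteria included dementia
exclusion	absence of dementia
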