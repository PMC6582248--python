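rule_id	event_label	event_class	observed_chrom	observed_arm	expected_chrom	expected_arm
inv4A_L_to_S	4AL->4AS	pericentromeric_inversion	4A	S	4A	L
inv4A_S_to_L	4AS->4AL	pericentromeric_inversion	4A	L	4A	S
rt_4AL_to_5AL	4AL->5AL	reciprocal_translocation	5A	L	4A	L
rt_5AL_to_4AL	5AL->4AL	reciprocal_translocation	4A	L	5A	L
tr_7BS_to_4AL	7BS->4AL	translocation	4A	L	7B	S
tr_5AL_to_7BS	5AL->7BS	translocation	7B	S	5A	L
tr_5BS_to_4BL	5BS->4BL	translocation	4B	L	5B	S
inv6B_S_to_L	6BS->6BL	putative_pericentromeric_inversion	6B	L	6B	S
inv6B_L_to_S	6BL->6BS	putative_pericentromeric_inversion	6B	S	6B	L
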