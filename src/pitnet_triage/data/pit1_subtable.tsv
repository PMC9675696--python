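rule_id	acidophil	immature	monomorphous	GH	PRL	TSH	type	warning
P7-ASC	true	*	*	*	*	*	acidophil_stem_cell
P7-IMM	*	true	*	*	*	*	immature_PIT1
P7-SOM	*	*	*	+	-	-	somatotroph
P7-LAC	*	*	*	-	+	-	lactotroph
P7-THY	*	*	*	-	-	+	thyrotroph
P7-MSM	*	*	true	+	+	-	mammosomatotroph
P7-MIX	*	*	false	+	+	-	mixed_somatotroph_lactotroph
P7-MSM-DEFAULT	*	*	absent	+	+	-	mammosomatotroph	monomorphous flag not assessed; mammosomatotroph assumed over mixed somatotroph-lactotroph
P7-MPH-GPT	*	*	*	+	+	+	mature_plurihormonal_PIT1
P7-MPH-GT	*	*	*	+	-	+	mature_plurihormonal_PIT1
P7-MPH-PT	*	*	*	-	+	+	mature_plurihormonal_PIT1
P7-SIL	*	*	*	-	-	-	immature_PIT1	hormone-silent PIT1 tumour; immature PIT1 lineage assumed
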