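cog_id	category	gene_examples	ambiguous_synthesis
COG0370	Fe(II)	feoB	false
COG1918	Fe(II)	feoA	false
COG2822	Fe(II)	efeO	false
COG1629	Fe(III)-OM	fhuA, cirA	false
COG4771	Fe(III)-OM	fepA	false
COG4773	Fe(III)-OM	fhuE	false
COG0609	Fe(III)-CM	fhuB, fepD	false
COG0614	Fe(III)-CM	fhuD, fepB	false
COG1120	Fe(III)-CM	fhuC, fepC	false
COG0803	divalent_cation	sitA, znuA	false
COG1108	divalent_cation	mntB, sitC	false
COG1121	divalent_cation	znuC, mntA	false
COG4772	dicitrate	fecA	false
COG1178	dicitrate	fecD	false
COG4774	heme	hemR	false
COG4558	heme	hmuT	false
COG4559	heme	hmuV	false
COG1528	storage	ftnA	false
COG2193	storage	bfr	false
COG0735	regulators	fur, zur	false
COG1321	regulators	dtxR, ideR	false
COG3712	regulators	fecR	false
COG1169	siderophore_synthesis	entC, pchA	true
COG0318	siderophore_synthesis	entE, dhbE, pvdI, asbC, acsA	true
COG1021	siderophore_synthesis	dhbE, entE	false
COG1020	siderophore_synthesis	entF, mbtB, pvdL	true
COG0031	siderophore_synthesis	sbnA	true
COG1535	siderophore_synthesis	entB	false
COG1819	siderophore_synthesis	iroB	false
COG3161	siderophore_synthesis	mbtI	false
COG3486	siderophore_synthesis	mbtG, alcA, pvdA	false
COG4362	siderophore_synthesis	mxcL	false
COG4264	siderophore_synthesis	iucA, alcB, asbA, sbnC	false
COG3475	siderophore_synthesis	asbF	false
COG4947	siderophore_synthesis	alcD	false
COG3182	siderophore_synthesis	sfaA	false
COG3962	siderophore_synthesis	sbnH	false
COG2366	siderophore_synthesis	pvdQ	false
COG4545	siderophore_synthesis	pchB	false
COG4907	siderophore_synthesis	ybtU	false
COG4929	siderophore_synthesis	ampD	false
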