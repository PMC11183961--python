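pathway_id	gene_id	cog_id	ambiguous_flag
enterobactin	entC	COG1169	true
enterobactin	entE	COG0318	true
enterobactin	entE	COG1021	false
enterobactin	entF	COG1020	true
enterobactin	entB	COG1535	false
salmochelin	entC	COG1169	true
salmochelin	entE	COG0318	true
salmochelin	entE	COG1021	false
salmochelin	iroB	COG1819	false
mycobactin	mbtA	COG0318	true
mycobactin	mbtB	COG1020	true
mycobactin	mbtG	COG3486	false
mycobactin	mbtI	COG3161	false
myxochelin	mxcE	COG0318	true
myxochelin	mxcF	COG1020	true
myxochelin	mxcL	COG4362	false
petrobactin	asbA	COG4264	false
petrobactin	asbB	COG4264	false
petrobactin	asbC	COG0318	true
petrobactin	asbF	COG3475	false
alcaligin	alcA	COG3486	false
alcaligin	alcB	COG4264	false
alcaligin	alcC	COG4264	false
alcaligin	alcD	COG4947	false
staphyloferrin_A	sfaB	COG4264	false
staphyloferrin_A	sfaD	COG4264	false
staphyloferrin_A	sfaA	COG3182	false
staphyloferrin_B	sbnA	COG0031	true
staphyloferrin_B	sbnC	COG4264	false
staphyloferrin_B	sbnE	COG4264	false
staphyloferrin_B	sbnH	COG3962	false
pyoverdin	pvdL	COG1020	true
pyoverdin	pvdI	COG0318	true
pyoverdin	pvdI	COG1020	true
pyoverdin	pvdA	COG3486	false
pyoverdin	pvdQ	COG2366	false
pyochelin	pchA	COG1169	true
pyochelin	pchD	COG0318	true
pyochelin	pchE	COG1020	true
pyochelin	pchB	COG4545	false
yersiniabactin	ybtE	COG0318	true
yersiniabactin	irp1	COG1020	true
yersiniabactin	irp2	COG1020	true
yersiniabactin	ybtU	COG4907	false
amphibactin	ampA	COG3486	false
amphibactin	ampB	COG1020	true
amphibactin	ampC	COG0318	true
amphibactin	ampD	COG4929	false
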