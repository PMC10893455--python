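class_name	drug_name
cyp2d6_inhibitors	fluoxetine
cyp2d6_inhibitors	paroxetine
cyp2d6_inhibitors	bupropion
cyp2d6_inhibitors	quinidine
cyp2d6_inhibitors	duloxetine
cyp2d6_inhibitors	terbinafine
cyp2d6_inhibitors	cinacalcet
cyp2d6_inhibitors	mirabegron
opioids	morphine
opioids	oxycodone
opioids	fentanyl
opioids	hydromorphone
opioids	hydrocodone
opioids	codeine
opioids	methadone
opioids	buprenorphine
opioids	sufentanil
opioids	pethidine
benzodiazepines	diazepam
benzodiazepines	alprazolam
benzodiazepines	lorazepam
benzodiazepines	clonazepam
benzodiazepines	midazolam
benzodiazepines	temazepam
benzodiazepines	oxazepam
antidepressants	fluoxetine
antidepressants	paroxetine
antidepressants	sertraline
antidepressants	citalopram
antidepressants	escitalopram
antidepressants	venlafaxine
antidepressants	duloxetine
antidepressants	amitriptyline
antidepressants	mirtazapine
antidepressants	trazodone
antidepressants	bupropion
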