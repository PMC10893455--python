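factor	category	acrd	non_acrd
sex	male	438	49639
sex	female	589	85088
age3	le17	111	3711
age3	a18_64	624	83060
age3	ge65	213	35983
region	americas	567	24494
region	europe	437	25557
region	asia	86	86116
region	oceania	31	2332
region	africa	5	1096
reporter	physician	498	36337
reporter	pharmacist	160	14414
reporter	other_hcp	232	31545
reporter	consumer	113	42305
reporter	lawyer	13	708
cyp2d6_inhibitors	user	136	5063
cyp2d6_inhibitors	non_user	990	134532
opioids	user	350	9340
opioids	non_user	776	130255
benzodiazepines	user	223	3919
benzodiazepines	non_user	903	135676
antidepressants	user	226	6403
antidepressants	non_user	900	133192
abuse	abuser	142	3248
abuse	non_abuser	984	136347
death	death	233	3377
death	survival	893	136218
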