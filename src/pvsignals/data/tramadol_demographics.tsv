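block	category	tramadol_all	tramadol_acrd	combination_all	combination_acrd
total	reports	140721	1126	51401	108
sex	male	50077	438	15571	44
sex	female	85677	589	34781	60
sex	unknown	4967	99	1049	4
age	le11	1172	67	142	0
age	a12_17	2650	44	464	5
age	a18_44	38203	350	8734	27
age	a45_64	45481	274	18596	22
age	a65_74	19300	96	10071	18
age	ge75	16896	117	9069	20
age	unknown	17019	178	4325	16
reporter	consumer	27818	113	11483	9
reporter	physician	37733	498	10458	64
reporter	other_hcp	44831	232	16375	15
reporter	pharmacist	15237	160	11794	16
reporter	lawyer	721	13	15	0
reporter	unknown	14381	110	1276	4
serious	serious	25562	938	5047	94
region	americas	25061	567	1319	34
region	europe	25994	437	7018	42
region	asia	86202	86	42846	31
region	oceania	2363	31	6	0
region	africa	1101	5	212	1
year	le2013	35328	502	7515	36
year	y2014	12671	127	4640	22
year	y2015	13902	79	5437	7
year	y2016	11554	70	3517	14
year	y2017	15894	56	7925	9
year	y2018	15590	105	7310	8
year	y2019	15615	89	6594	8
year	ge2020	20167	98	8463	4
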