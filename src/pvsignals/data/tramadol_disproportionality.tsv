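drug	term	n	prr	prr_lo	prr_hi	ror	ror_lo	ror_hi	ic025
tramadol	Respiratory arrest	358	2.91	2.62	3.23	2.92	2.63	3.24	1.37
tramadol	Respiratory depression	357	5.52	4.97	6.13	5.53	4.98	6.15	2.26
tramadol	Respiratory failure	129	0.56	0.47	0.67	0.56	0.47	0.67	-1.08
tramadol	Bradypnoea	73	8.93	7.06	11.3	8.93	7.06	11.3	2.67
tramadol	Apnoea	69	0.62	0.49	0.78	0.62	0.49	0.78	-1.05
tramadol	Hypoventilation	60	2.19	1.70	2.83	2.19	1.70	2.83	0.72
tramadol	Respiratory rate decreased	34	2.22	1.58	3.11	2.22	1.58	3.11	0.59
tramadol	Acute respiratory failure	33	0.68	0.48	0.96	0.68	0.48	0.96	-1.08
tramadol	Hypopnoea	29	1.91	1.32	2.75	1.91	1.32	2.75	0.33
tramadol	Acute respiratory distress syndrome	24	0.47	0.31	0.70	0.47	0.31	0.70	-1.70
tramadol	Apnoeic attack	6	1.74	0.78	3.88	1.74	0.78	3.88	-0.66
tramadol	Breath holding	6	1.18	0.53	2.63	1.18	0.53	2.63	-1.16
tramadol	Infantile apnoea	6	1.15	0.51	2.56	1.15	0.51	2.56	-1.20
tramadol	Breath sounds abnormal	5	0.28	0.16	0.67	0.28	0.16	0.67	-3.27
tramadol	Neonatal respiratory depression	4	1.86	0.70	4.99	1.86	0.70	4.99	-0.98
tramadol	Apparent life threatening event	2	0.50	0.13	2.01	0.50	0.13	2.01	-3.43
tramadol	Neonatal respiratory arrest	1	1.77	0.25	12.7	1.77	0.25	12.7	-3.31
tramadol	Respiratory depth decreased	1	2.37	0.33	17.1	2.37	0.33	17.1	-3.10
tramadol	Respiratory paralysis	1	1.09	0.15	7.80	1.09	0.15	7.80	-3.71
tramadol/paracetamol	Respiratory arrest	13	0.29	0.17	0.49	0.29	0.17	0.49	-2.66
tramadol/paracetamol	Respiratory depression	35	1.44	1.04	2.01	1.45	1.04	2.01	0.003
tramadol/paracetamol	Respiratory failure	20	0.24	0.15	0.37	0.24	0.15	0.37	-2.73
tramadol/paracetamol	Bradypnoea	10	3.21	1.73	5.99	3.21	1.73	5.99	0.50
tramadol/paracetamol	Apnoea	6	0.15	0.04	0.33	0.15	0.04	0.33	-4.04
tramadol/paracetamol	Hypoventilation	4	0.40	0.15	1.06	0.40	0.15	1.06	-2.97
tramadol/paracetamol	Respiratory rate decreased	7	1.24	0.59	2.61	1.24	0.59	2.61	-0.97
tramadol/paracetamol	Acute respiratory failure	7	0.39	0.19	0.83	0.39	0.19	0.83	-2.54
tramadol/paracetamol	Hypopnoea	4	0.72	0.27	1.91	0.72	0.27	1.91	-2.17
tramadol/paracetamol	Acute respiratory distress syndrome	3	0.16	0.05	0.50	0.16	0.05	0.50	-4.50
tramadol/paracetamol	Apnoeic attack	0	NA	NA	NA	NA	NA	NA	NA
tramadol/paracetamol	Breath holding	1	0.54	0.08	3.81	0.54	0.08	3.81	-4.45
tramadol/paracetamol	Infantile apnoea	0	NA	NA	NA	NA	NA	NA	NA
tramadol/paracetamol	Breath sounds abnormal	2	0.30	0.08	1.22	0.30	0.08	1.22	-4.08
tramadol/paracetamol	Neonatal respiratory depression	0	NA	NA	NA	NA	NA	NA	NA
tramadol/paracetamol	Apparent life threatening event	0	NA	NA	NA	NA	NA	NA	NA
tramadol/paracetamol	Neonatal respiratory arrest	0	NA	NA	NA	NA	NA	NA	NA
tramadol/paracetamol	Respiratory depth decreased	0	NA	NA	NA	NA	NA	NA	NA
tramadol/paracetamol	Respiratory paralysis	0	NA	NA	NA	NA	NA	NA	NA
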