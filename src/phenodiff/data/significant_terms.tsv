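term_id	label	enriched_group	count_synthesis	count_tr	pct_synthesis	pct_tr	p_corrected
HP:0011297	Abnormality of digit	synthesis	31	4	33.3	6.8	0.03185
HP:0011805	Abnormal muscle morphology	synthesis	25	2	26.9	3.4	0.04678
HP:0011927	Short digit	synthesis	22	1	23.7	1.7	0.04883
HP:0001367	Abnormal joint morphology	synthesis	22	1	23.7	1.7	0.04883
HP:0100261	Abnormal tendon morphology	synthesis	19	0	20.4	0.0	0.04346
HP:0002360	Sleep disturbance	transamidase_remodeling	0	13	0.00	22.03	0.00047
HP:0012759	Neurodevelopmental abnormality	transamidase_remodeling	68	58	73.12	98.31	0.01235
HP:0000708	Behavioral abnormality	transamidase_remodeling	14	25	15.05	42.37	0.03610
HP:0012758	Neurodevelopmental delay	transamidase_remodeling	57	54	61.29	91.53	0.00898
HP:0001249	Intellectual disability	transamidase_remodeling	15	39	16.13	66.10	0.00000
HP:0003330	Abnormal bone structure	transamidase_remodeling	3	15	3.23	25.42	0.00773
HP:0011849	Abnormal bone ossification	transamidase_remodeling	2	15	2.15	25.42	0.00193
HP:0004348	Abnormality of bone mineral density	transamidase_remodeling	2	15	2.15	25.42	0.00193
HP:0004349	Reduced bone mineral density	transamidase_remodeling	2	15	2.15	25.42	0.00193
HP:0000938	Osteopenia	transamidase_remodeling	2	13	2.15	22.03	0.01305
HP:0000400	Macrotia	transamidase_remodeling	2	15	2.15	25.42	0.00193
HP:0002265	Large fleshy ears	transamidase_remodeling	1	14	1.08	23.73	0.00106
HP:0000366	Abnormality of the nose	transamidase_remodeling	26	36	27.96	61.02	0.01119
HP:0100737	Abnormal hard palate morphology	transamidase_remodeling	6	17	6.45	28.81	0.03743
HP:0000202	Oral cleft	transamidase_remodeling	6	18	6.45	30.51	0.01556
HP:0000175	Cleft palate	transamidase_remodeling	6	17	6.45	28.81	0.03743
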