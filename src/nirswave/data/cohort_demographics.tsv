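subject_id	sex	age	etiology	hemiplegia_side	lesion_side	lesion_site	time_since_onset_months	mmt_grade
Pt01	Male	54	Infarction	left	right	Frontotemporal-parietal	0.9	0
Pt02	Male	45	Hemorrhage	right	left	External capsule	2.77	1
Pt03	Female	78	Infarction	left	right	Internal capsule	0.4	1
Pt04	Female	80	Infarction	right	left	Pons	2.27	4
Pt05	Male	84	Infarction	left	right	Cerebellum	1.13	2
Pt06	Female	43	Infarction	right	left	Basal ganglia	0.5	4
Pt07	Male	62	Infarction	right	left	Temporal lobe	0.67	5
Pt08	Male	62	Infarction	right	left	Frontoparietal	0.9	4
Pt09	Male	70	Infarction	left	right	Basal ganglia	1.33	1
Pt10	Male	58	Hemorrhage	right	left	Basal ganglia	1.07	2
Pt11	Male	33	Infarction	right	left	Middle cerebral artery	2.43	2
Pt12	Male	50	Infarction	left	right	Frontoparietal lobe	2.3	5
Pt13	Male	64	Infarction	left	right	Vertebral artery	3.97	1
Pt14	Female	64	Infarction	right	left	Pons	1.63	2
Pt15	Male	68	Infarction	right	left	Basal ganglia	1.43	2
Pt16	Male	45	Infarction	right	left	Basal ganglia	4.9	2
Pt17	Male	43	Hemorrhage	left	right	Pons	1.43	4
Pt18	Female	62	Hemorrhage	left	right	Parietal lobe	4.01	1
Pt19	Male	89	Infarction	left	right	Pons	2.5	2
Pt20	Male	32	Hemorrhage	left	right	Parietal lobe	2.53	4
Pt21	Male	65	Infarction	left	right	Basal ganglia	2.37	2
Pt22	Female	63	Infarction	right	left	Pons	0.7	4
Pt23	Male	55	Hemorrhage	left	right	Basal ganglia	0.6	0
Pt24	Male	60	Hemorrhage	left	right	External capsule	0.67	2
Pt25	Male	50	Infarction	right	left	Basal ganglia	0.43	3
Pt26	Female	73	Infarction	right	left	Corona radiata	1.2	1
Pt27	Male	44	Infarction	right	left	Basal ganglia	1.27	2
Pt28	Male	50	Infarction	right	left	Vertebral artery	0.4	0
Pt29	Male	42	Hemorrhage	left	right	Basal ganglia	0.27	2
Pt30	Female	55	Infarction	right	left	Basal ganglia	5.8	2
Pt31	Male	54	Hemorrhage	left	right	Basal ganglia	2.07	3
Pt32	Female	72	Infarction	right	left	Internal capsule	2.33	2
Pt33	Male	35	Hemorrhage	left	right	Basal ganglia	4.8	1
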