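# radbed default radiobiological parameter / DV-constraint database.
# ILLUSTRATIVE PLACEHOLDER VALUES ONLY (literature-style, e.g. Emami/Burman-type
# fitting ranges) — NOT clinically validated. Edit to your institute's data.
# Tab-separated; constraint limits are stated at 2 Gy per fraction.
record	name	kind	alpha_beta_gy	alpha_per_gy	clonogen_number	td50_whole_gy	slope_m	volume_exponent	volume	volume_unit	limit_dose_2gy_gy	endpoint	citation
parameter	prostate	tumor	1.5	0.15	1e6
parameter	generic tumor	tumor	10	0.3	1e7
parameter	rectum	oar	3			80	0.15	0.12
parameter	bladder	oar	3			80	0.11	0.5
parameter	femoral head	oar	3			65	0.12	0.25
parameter	intestine	oar	3			55	0.16	0.15
parameter	spinal cord	oar	2			66.5	0.175	0.05
parameter	brain stem	oar	2			65	0.14	0.16
parameter	optic nerve	oar	2			65	0.14	0.25
parameter	chiasm	oar	2			65	0.14	0.25
parameter	lens	oar	1.2			18	0.27	0.3
parameter	larynx	oar	3			70	0.17	0.08
parameter	parotid	oar	3			46	0.4	0.7
parameter	lung	oar	3			24.5	0.18	0.87
parameter	esophagus	oar	3			68	0.11	0.06
parameter	heart	oar	3			48	0.1	0.35
constraint	rectum	oar							0.3	fraction	70	grade>=2 proctitis
constraint	rectum	oar							0.5	fraction	60	grade>=2 proctitis
constraint	bladder	oar							0.5	fraction	65	grade>=3 cystitis
constraint	femoral head	oar							0.05	fraction	50	necrosis
constraint	intestine	oar							0.3	fraction	45	obstruction
constraint	spinal cord	oar							1	fraction	45	myelopathy
constraint	brain stem	oar							1	fraction	54	necrosis
constraint	optic nerve	oar							1	fraction	54	neuropathy
constraint	chiasm	oar							1	fraction	54	neuropathy
constraint	lens	oar							1	fraction	10	cataract
constraint	larynx	oar							1	fraction	66	edema
constraint	parotid	oar							1	fraction	32	mean dose, xerostomia
constraint	lung	oar							0.3	fraction	20	pneumonitis
constraint	esophagus	oar							0.3	fraction	55	stricture
constraint	heart	oar							0.3	fraction	46	pericarditis
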