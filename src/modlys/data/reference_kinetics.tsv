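# Published first-order thermal-inactivation constants for native and
# chemically modified laccase variants incubated at 60 degrees C.
# kd_e4: inactivation rate constant x 1e4 (1/min); t_half: minutes;
# R: half-life ratio vs the matching control (blank for controls).
# control column names the control variant each R is computed against.
variant	kd_e4	t_half	R	control
EM_control	31.55	219.7		EM_control
Glc-ver-EM	44.81	154.7	0.7	EM_control
Glc-EM	53.36	129.9	0.6	EM_control
Gal-ver-EM	27.45	252.5	1.1	EM_control
Gal-EM	59.55	116.4	0.5	EM_control
Cel-ver-EM	39.54	175.3	0.8	EM_control
Cel-EM	48.10	144.1	0.7	EM_control
Lac-ver-EM	38.90	178.2	0.8	EM_control
Lac-EM	70.87	97.8	0.4	EM_control
GA-ver-EM	45.27	153.1	0.7	EM_control
GA-EM	62.17	111.5	0.5	EM_control
CDI-ver-EM	50.30	137.8	0.6	EM_control
CDI-EM	26.18	264.8	1.2	EM_control
GA-CDI-ver-EM	7.38	938.7	4.3	EM_control
GA-CDI-EM	20.70	334.9	1.5	EM_control
NHSP-ver-EM	110.02	63.0	0.3	EM_control
NHSP-EM	108.99	63.6	0.3	EM_control
CA-EM	116.11	59.7	0.3	EM_control
EGNHS-EM	25.46	272.2	1.2	EM_control
PS-EM	15.85	437.3	2.0	EM_control
CU_control	145.31	47.7		CU_control
CA-CU	3.88	1787.4	37.5	CU_control
EGNHS-CU	62.39	111.1	2.3	CU_control
PS-CU	11.54	600.8	12.6	CU_control
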