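target	pdb_id	ligand_type	assigned	rigid_score	rigid_volume	flex_score	flex_volume
Bcl-xL	2bzw	protein	druggable	1.5	112	2.4	172
Bcl-2	2xa0	protein	druggable	1.5	167	2.0	174
HDM2	1ycr	protein	druggable	1.7	165	2.5	175
TNFa	1tnf	protein	difficult	1.8	126	2.4	257
IL-2Ra	1z92	protein	difficult	0.9	49	*	*
HPV-E2	1tue	protein	difficult	0.8	57	*	*
ZipA	1f46	protein	difficult	0.7	105	*	*
ZipA	1f47	protein	difficult	0.9	141	*	*
Bcl-xL	2yxj	cmpd	druggable	1.8	141	2.5	239
Bcl-xL	3qkd	cmpd	druggable	1.9	132	2.1	195
Bcl-xL	4ehr	cmpd	druggable	1.4	100	2.4	175
Bcl-2	4aq3	cmpd	druggable	1.7	113	2.3	220
HDM2	1rv1	cmpd	druggable	1.7	147	2.2	178
HDM2	1t4e	cmpd	druggable	1.6	203	2.1	234
HDM2	3jzk	cmpd	druggable	1.6	204	1.9	184
HDM2	3lbk	cmpd	druggable	1.5	150	1.9	160
HDM2	3lbl	cmpd	druggable	2.0	224	2.2	218
HDM2	3tu1	cmpd	druggable	1.5	221	1.9	172
HDM2	4dij	cmpd	druggable	1.6	192	1.8	207
HDM2	4ere	cmpd	druggable	1.8	165	2.5	172
TNFa	2az5	cmpd	difficult	1.7	325	2.0	233
TNFR1	1ft4	cmpd	difficult	1.2	330	*	*
IL-2Ra	1py2	cmpd	difficult	1.2	66	*	*
IL-2Ra	1pw6	cmpd	difficult	1.4	73	1.4	72
HPV-E2	1r6n	cmpd	difficult	1.2	95	*	*
ZipA	1y2f	cmpd	difficult	0.9	91	*	*
ZipA	1y2g	cmpd	difficult	0.9	96	*	*
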