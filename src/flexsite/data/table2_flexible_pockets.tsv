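target	pdb_id	dock_hit_rate	flex_dscore_plus
CDK2	1aq1	1.32	1.7
CDK2	1buh	1.44	1.7
CDK2	1dm2	1.62	1.9
ER	1l2i	1.69	2.9
ER	3ert	1.55	2.7
ER	1err	1.61	2.8
HIV-RT	1vrt	1.66	2.5
HIV-RT	1rt1	1.75	2.3
HIV-RT	1c1c	1.61	2.2
HIV-RT	1rth	1.61	2.3
p38a	1a9u	1.00	1.8
p38a	1kv1	1.16	2.1
p38a	1kv2	1.61	2.1
PPARg	1fm6	1.46	2.9
PPARg	1fm9	1.62	3.0
PPARg	2prg	1.43	2.1
TK	1kim	1.58	2.7
TK	1ki4	1.40	2.6
IL-2	1z92	0.13	1.5
IL-2	1py2	0.62	1.5
IL-2	1m48	0.62	1.7
Bcl-xL	2bzw	1.04	2.4
Bcl-xL	2yxj	0.84	2.5
TNF	1tnf	0.95	2.4
TNF	2az5	0.96	2.0
MDM2	1ycr	0.45	2.5
MDM2	1rv1	0.92	2.2
MDM2	1t4e	0.66	2.1
HPV-E2	1tue	-0.24	1.1
HPV-E2	1r6n	1.02	1.5
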