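icd10_3	category
I10	hypertension
I11	hypertension
I12	hypertension
I13	hypertension
I15	hypertension
I16	hypertension
E78	hyperlipidemia
E08	diabetes
E09	diabetes
E10	diabetes
E11	diabetes
E13	diabetes
M05	arthritis
M06	arthritis
M08	arthritis
M15	arthritis
M16	arthritis
M17	arthritis
M18	arthritis
M19	arthritis
M45	arthritis
I20	cardiovascular disease
I21	cardiovascular disease
I22	cardiovascular disease
I24	cardiovascular disease
I25	cardiovascular disease
I65	cardiovascular disease
I66	cardiovascular disease
I67	cardiovascular disease
I70	cardiovascular disease
I71	cardiovascular disease
I73	cardiovascular disease
I74	cardiovascular disease
I42	heart failure
I43	heart failure
I50	heart failure
J40	asthma/COPD
J41	asthma/COPD
J42	asthma/COPD
J43	asthma/COPD
J44	asthma/COPD
J45	asthma/COPD
J47	asthma/COPD
M40	musculoskeletal disorder
M41	musculoskeletal disorder
M42	musculoskeletal disorder
M43	musculoskeletal disorder
M46	musculoskeletal disorder
M47	musculoskeletal disorder
M48	musculoskeletal disorder
M50	musculoskeletal disorder
M51	musculoskeletal disorder
M53	musculoskeletal disorder
M54	musculoskeletal disorder
E00	thyroid disorder
E01	thyroid disorder
E02	thyroid disorder
E03	thyroid disorder
E04	thyroid disorder
E05	thyroid disorder
E06	thyroid disorder
E07	thyroid disorder
K20	stomach problem
K21	stomach problem
K25	stomach problem
K26	stomach problem
K27	stomach problem
K28	stomach problem
K29	stomach problem
K30	stomach problem
K31	stomach problem
N30	urinary problem
N31	urinary problem
N32	urinary problem
N39	urinary problem
N40	urinary problem
R32	urinary problem
F32	anxiety/depression
F33	anxiety/depression
F34	anxiety/depression
F40	anxiety/depression
F41	anxiety/depression
F42	anxiety/depression
F43	anxiety/depression
F48	anxiety/depression
C00	cancer
C01	cancer
C02	cancer
C03	cancer
C04	cancer
C05	cancer
C06	cancer
C07	cancer
C08	cancer
C09	cancer
C10	cancer
C11	cancer
C12	cancer
C13	cancer
C14	cancer
C15	cancer
C16	cancer
C17	cancer
C18	cancer
C19	cancer
C20	cancer
C21	cancer
C22	cancer
C23	cancer
C24	cancer
C25	cancer
C26	cancer
C27	cancer
C28	cancer
C29	cancer
C30	cancer
C31	cancer
C32	cancer
C33	cancer
C34	cancer
C35	cancer
C36	cancer
C37	cancer
C38	cancer
C39	cancer
C40	cancer
C41	cancer
C42	cancer
C43	cancer
C44	cancer
C45	cancer
C47	cancer
C48	cancer
C49	cancer
C50	cancer
C51	cancer
C52	cancer
C53	cancer
C54	cancer
C55	cancer
C56	cancer
C57	cancer
C58	cancer
C59	cancer
C60	cancer
C61	cancer
C62	cancer
C63	cancer
C64	cancer
C65	cancer
C66	cancer
C67	cancer
C68	cancer
C69	cancer
C70	cancer
C71	cancer
C72	cancer
C73	cancer
C74	cancer
C75	cancer
C76	cancer
C77	cancer
C78	cancer
C79	cancer
C80	cancer
C81	cancer
C82	cancer
C83	cancer
C84	cancer
C85	cancer
C86	cancer
C87	cancer
C88	cancer
C89	cancer
C90	cancer
C91	cancer
C92	cancer
C93	cancer
C94	cancer
C95	cancer
C96	cancer
C46	cancer
D05	cancer
D06	cancer
N17	kidney disease
N18	kidney disease
N19	kidney disease
N03	kidney disease
N05	kidney disease
B18	liver disease
K70	liver disease
K71	liver disease
K72	liver disease
K73	liver disease
K74	liver disease
K75	liver disease
K76	liver disease
F01	dementia
F02	dementia
F03	dementia
G30	dementia
G31	dementia
M80	osteoporosis
M81	osteoporosis
G45	stroke/TIA
I60	stroke/TIA
I61	stroke/TIA
I62	stroke/TIA
I63	stroke/TIA
I64	stroke/TIA
I69	stroke/TIA
G40	epilepsy
G41	epilepsy
F10	substance use
F11	substance use
F12	substance use
F13	substance use
F14	substance use
F15	substance use
F16	substance use
F18	substance use
F19	substance use
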