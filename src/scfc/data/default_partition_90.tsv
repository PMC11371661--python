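# Synthetic default five-module partition of a 90-region parcellation.
# Module sizes: auditory_motor 20, vision 14, attention 18, dmn 18, limbic_subcortical 20.
# Replace with your own two-column region<TAB>module table for real atlas assignments.
R01	auditory_motor
R02	auditory_motor
R03	auditory_motor
R04	auditory_motor
R05	auditory_motor
R06	auditory_motor
R07	auditory_motor
R08	auditory_motor
R09	auditory_motor
R10	auditory_motor
R11	auditory_motor
R12	auditory_motor
R13	auditory_motor
R14	auditory_motor
R15	auditory_motor
R16	auditory_motor
R17	auditory_motor
R18	auditory_motor
R19	auditory_motor
R20	auditory_motor
R21	vision
R22	vision
R23	vision
R24	vision
R25	vision
R26	vision
R27	vision
R28	vision
R29	vision
R30	vision
R31	vision
R32	vision
R33	vision
R34	vision
R35	attention
R36	attention
R37	attention
R38	attention
R39	attention
R40	attention
R41	attention
R42	attention
R43	attention
R44	attention
R45	attention
R46	attention
R47	attention
R48	attention
R49	attention
R50	attention
R51	attention
R52	attention
R53	dmn
R54	dmn
R55	dmn
R56	dmn
R57	dmn
R58	dmn
R59	dmn
R60	dmn
R61	dmn
R62	dmn
R63	dmn
R64	dmn
R65	dmn
R66	dmn
R67	dmn
R68	dmn
R69	dmn
R70	dmn
R71	limbic_subcortical
R72	limbic_subcortical
R73	limbic_subcortical
R74	limbic_subcortical
R75	limbic_subcortical
R76	limbic_subcortical
R77	limbic_subcortical
R78	limbic_subcortical
R79	limbic_subcortical
R80	limbic_subcortical
R81	limbic_subcortical
R82	limbic_subcortical
R83	limbic_subcortical
R84	limbic_subcortical
R85	limbic_subcortical
R86	limbic_subcortical
R87	limbic_subcortical
R88	limbic_subcortical
R89	limbic_subcortical
R90	limbic_subcortical
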