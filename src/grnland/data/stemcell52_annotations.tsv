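# name	id	role
OCT4	1	stem_marker
SOX2	2	stem_marker
NANOG	3	stem_marker
OCT4SOX2	4	stem_marker
KLF4	5	stem_marker
FOXD3	6	stem_marker
ZIC3	7	stem_marker
ZFP42	8	stem_marker
GDF3	9	stem_marker
TDGF1	10	stem_marker
PBX1	11	stem_marker
FOXA2	12	diff_marker
AFP	13	diff_marker
SOX17	14	diff_marker
GATA4	15	diff_marker
GATA6	16	diff_marker
T	17	diff_marker
GATA2	18	diff_marker
GATA3	19	diff_marker
HCGA	20	diff_marker
HCGB	21	diff_marker
CDX2	22	diff_marker
PRDM14	23	stem_activated
LMCD1	24	stem_activated
G25	25	stem_activated
G26	26	stem_activated
G27	27	stem_activated
G28	28	stem_activated
G29	29	stem_activated
G30	30	stem_activated
G31	31	stem_activated
G32	32	stem_activated
G33	33	stem_activated
G34	34	stem_activated
G35	35	stem_activated
G36	36	stem_activated
G37	37	stem_activated
G38	38	stem_activated
G39	39	other
G40	40	other
G41	41	other
G42	42	other
G43	43	other
G44	44	other
G45	45	other
G46	46	other
G47	47	other
G48	48	other
G49	49	other
G50	50	other
G51	51	other
G52	52	other
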