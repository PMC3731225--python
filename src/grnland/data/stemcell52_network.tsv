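# source	sign	target	provenance
NANOG	act	OCT4	text
OCT4SOX2	act	OCT4	text
NANOG	act	SOX2	text
OCT4SOX2	act	SOX2	text
NANOG	act	NANOG	text
OCT4SOX2	act	NANOG	text
KLF4	act	NANOG	text
ZIC3	act	NANOG	text
PBX1	act	NANOG	text
OCT4	act	OCT4SOX2	text
SOX2	act	OCT4SOX2	text
SOX2	act	ZIC3	text
NANOG	act	ZIC3	text
NANOG	act	PBX1	text
GATA6	act	GATA6	text
CDX2	act	CDX2	text
CDX2	rep	OCT4	text
OCT4	rep	GATA6	text
NANOG	rep	GATA6	text
GATA4	rep	GATA6	text
LMCD1	rep	GATA6	text
PRDM14	rep	GATA6	text
GATA6	rep	NANOG	text
OCT4	rep	CDX2	text
OCT4SOX2	act	KLF4	synthetic
OCT4	act	KLF4	synthetic
OCT4	act	FOXD3	synthetic
NANOG	act	FOXD3	synthetic
OCT4	act	ZFP42	synthetic
SOX2	act	ZFP42	synthetic
OCT4	act	GDF3	synthetic
NANOG	act	GDF3	synthetic
OCT4	act	TDGF1	synthetic
NANOG	act	TDGF1	synthetic
OCT4	act	PRDM14	synthetic
NANOG	act	PRDM14	synthetic
OCT4	act	LMCD1	synthetic
SOX2	act	LMCD1	synthetic
GATA6	act	GATA4	synthetic
GATA6	act	FOXA2	synthetic
GATA4	act	AFP	synthetic
FOXA2	act	AFP	synthetic
GATA6	act	SOX17	synthetic
GATA4	act	SOX17	synthetic
CDX2	act	T	synthetic
CDX2	act	GATA2	synthetic
GATA6	act	GATA2	synthetic
CDX2	act	GATA3	synthetic
GATA2	act	HCGA	synthetic
GATA3	act	HCGA	synthetic
GATA2	act	HCGB	synthetic
GATA3	act	HCGB	synthetic
OCT4	act	G25	synthetic
OCT4SOX2	act	G25	synthetic
SOX2	act	G26	synthetic
KLF4	act	G26	synthetic
NANOG	act	G27	synthetic
FOXD3	act	G27	synthetic
OCT4SOX2	act	G28	synthetic
ZIC3	act	G28	synthetic
KLF4	act	G29	synthetic
OCT4	act	G29	synthetic
FOXD3	act	G30	synthetic
SOX2	act	G30	synthetic
ZIC3	act	G31	synthetic
NANOG	act	G31	synthetic
OCT4	act	G32	synthetic
OCT4SOX2	act	G32	synthetic
SOX2	act	G33	synthetic
KLF4	act	G33	synthetic
NANOG	act	G34	synthetic
FOXD3	act	G34	synthetic
OCT4SOX2	act	G35	synthetic
ZIC3	act	G35	synthetic
KLF4	act	G36	synthetic
OCT4	act	G36	synthetic
OCT4	act	G37	synthetic
SOX2	act	G38	synthetic
GATA6	act	G39	synthetic
CDX2	act	G40	synthetic
GATA4	act	G41	synthetic
T	act	G42	synthetic
GATA2	act	G43	synthetic
GATA3	act	G44	synthetic
SOX17	act	G45	synthetic
G25	act	G46	synthetic
G26	act	G47	synthetic
G27	act	G48	synthetic
G28	act	G49	synthetic
G29	act	G50	synthetic
G30	act	G51	synthetic
G31	act	G52	synthetic
NANOG	rep	CDX2	synthetic
SOX2	rep	CDX2	synthetic
OCT4	rep	GATA4	synthetic
NANOG	rep	GATA4	synthetic
OCT4	rep	FOXA2	synthetic
NANOG	rep	FOXA2	synthetic
OCT4	rep	AFP	synthetic
SOX2	rep	AFP	synthetic
OCT4	rep	SOX17	synthetic
NANOG	rep	SOX17	synthetic
NANOG	rep	T	synthetic
SOX2	rep	T	synthetic
OCT4	rep	GATA2	synthetic
NANOG	rep	GATA2	synthetic
OCT4	rep	GATA3	synthetic
SOX2	rep	GATA3	synthetic
NANOG	rep	HCGA	synthetic
SOX2	rep	HCGA	synthetic
NANOG	rep	HCGB	synthetic
OCT4	rep	HCGB	synthetic
GATA6	rep	SOX2	synthetic
CDX2	rep	NANOG	synthetic
CDX2	rep	KLF4	synthetic
GATA6	rep	FOXD3	synthetic
CDX2	rep	PBX1	synthetic
GATA6	rep	ZFP42	synthetic
OCT4SOX2	rep	CDX2	synthetic
KLF4	rep	GATA6	synthetic
SOX17	rep	NANOG	synthetic
GATA4	rep	OCT4	synthetic
T	rep	TDGF1	synthetic
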