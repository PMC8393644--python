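# Host-pathogen interactome genes carrying rare deleterious variants in the
# familial-sarcoidosis (F-SARC) and control exome series, with the SARS-CoV-2
# protein (viral bait) each host gene product binds.
# Columns: gene_symbol <TAB> viral_bait <TAB> cohort flag
YIF1A	M	F-SARC + Control
PITRM1	M	F-SARC + Control
FASTKD5	M	F-SARC
STOM	M	F-SARC
AASS	M	F-SARC + Control
TBK1	Nsp13	F-SARC
GOLGA2	Nsp13	F-SARC
GOLGA3	Nsp13	F-SARC
GOLGA7	SPIKE	F-SARC
GOLGB1	Nsp13	F-SARC
TYSDN1	Nsp12	F-SARC + Control
ECSIT	Orf9b	F-SARC
NLRX1	Orf9b	F-SARC + Control
ACAD9	Orf9b	F-SARC + Control
PUSL1	Orf8	F-SARC + Control
DNAJC11	Nsp4	F-SARC + Control
BRD4	E	F-SARC + Control
VPS11	Orf3A	F-SARC
PDE4DIP	Nsp13	F-SARC
FYCO1	Nsp13	F-SARC + Control
HS2ST1	Nsp7	F-SARC
ZDHHC5	SPIKE	F-SARC
EMC1	Orf8	F-SARC
PLD3	Orf8	F-SARC + Control
GDF15	Orf8	F-SARC
FKBP10	Orf8	F-SARC + Control
ADAM9	Orf8	F-SARC + Control
IL17RA	Orf8	F-SARC + Control
PLAT	Orf8	F-SARC + Control
EXOSC2	Nsp8	F-SARC
UGGT2	Orf8	CTRL
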