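domain_name	functions	localization
Bac_PepC14	proteolysis;PCD-related
Peptidase_C14	proteolysis;PCD-related
WD40	protein-protein interaction
TPR_1	protein-protein interaction
TPR_2	protein-protein interaction
TPR_4	protein-protein interaction
Sel1	protein-protein interaction
FGE-sulfatase	protein modification
Polysacc_deac_1	enzymatic
NACHT	NTPase;PCD-related
NB-ARC	signaling;PCD-related
PG_binding_1	cell wall binding	extracellular
Amidase_2	enzymatic;cell wall binding
Lipase_GDSL	enzymatic
CHASE2	signaling	extracellular
ANF_receptor	signaling	extracellular
GGDEF	signaling	intracellular
GUN4	signaling	intracellular
AAA	NTPase;chaperone
AAA_5	NTPase
Prefoldin_2	chaperone
Pentapeptide	unknown
HEAT_PBS	protein-protein interaction
TIR	signaling;protein-protein interaction
Helicase_C	helicase;NTPase
DEAD	helicase;NTPase
Peptidase_S8	proteolysis
Lactamase_B	enzymatic
CBM_4_9	protein-carbohydrate interaction
OmpA	unknown	membrane
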