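gene	uniprot	family	delta_g
EXOSC3	Q9NQT5	RRP40 family	-33.0
MAPK12	P53778	Kinase family	-28.6
ITGAL	O43746	Integrin alpha chain family	-28.0
PTGS2	P35354	Prostaglandin G/H synthase family	-20.2
PTGS1	P23219	Prostaglandin G/H synthase family	-27.6
PLA2G10	O15496	Phospholipase A2 family	-25.7
FBP1	P09467	FBPase class 1 family	-25.3
CUL4B	Q13620	Cullin family	-23.0
MMP12	P39900	Peptidase M10A family	-18.6
CDK13	Q14004	kinase family	-18.4
TNFAIP6	P98066	Hyaluronan-binding protein family	-16.8
PLA2G3	Q9NZ20	Phospholipase A2 family	-14.7
HLA-A	O19619	MHC class I family	-12.1
MOCS3	O95396	HesA/MoeB/ThiF family	-12.0
AIDA	Q96BJ3	AIDA family	-11.1
RAC1	P63000	Rho family	-11.0
PLA2G5	P39877	Phospholipase A2 family	-10.8
PLA2G1B	P04054	Phospholipase A2 family	-10.6
PLA2G2A	P14555	Phospholipase A2 family	-10.6
TNFSF14	O43557	Tumor necrosis factor family	-10.3
CHIT1	Q13231	Chitotriosidase family	-10.0
EGFLAM	Q63HQ2	Pikachurin family	-9.2
PLA2G2D	Q9UNK4	Phospholipase A2 family	-6.0
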