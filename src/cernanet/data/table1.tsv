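gene	log2fc	p_value	mirnas	lncrnas	category	function
ACTC1	-3.4644	0.0122	gga-miR-6606-5p	MSTRG.19949.13,MSTRG.128588.3,MSTRG.73129.28,MSTRG.32082.2	angiogenesis	Blood circulation
KCNMB4	2.3558	0.0001	gga-miR-6606-5p	MSTRG.29252.7	angiogenesis	Vascular smooth muscle contraction
NCS1	-1.0050	0.0197	gga-miR-6606-5p,novel_miR_815	MSTRG.33345.5,MSTRG.140060.1,MSTRG.18943.13	angiogenesis	Calcium ion transport
NGFR	1.5519	0.0036	novel_miR_676	MSTRG.118362.24,MSTRG.12318.1,MSTRG.25780.4,MSTRG.128839.3,MSTRG.115756.46,MSTRG.41646.22,MSTRG.80622.27,MSTRG.44286.2,MSTRG.41646.23	angiogenesis	Blood vessel morphogenesis, blood vessel development, vasculature development, angiogenesis
ADAM8	-1.3727	0.0470			angiogenesis	Response to hypoxia, blood vessel development, vasculature development, angiogenesis
CASQ2	-1.0736	0.0315	novel_miR_589,novel_miR_676	MSTRG.73129.28,MSTRG.18943.3	angiogenesis	Blood circulation
IRF4	-1.8880	0.0201			angiogenesis	Hemopoiesis
PTPRZ1	1.3653	0.0000			angiogenesis	Hemopoiesis, hematopoietic progenitor cell differentiation
CALML3	-1.1958	0.0015			angiogenesis	Vascular smooth muscle contraction
ERBB4	-1.2949	0.0102	novel_miR_676,novel_miR_587	MSTRG.147643.141,MSTRG.128534.3,MSTRG.44329.1,MSTRG.29590.15,MSTRG.79818.8,MSTRG.135465.5,MSTRG.30620.3	angiogenesis	Calcium and MAPK signaling pathways
ARR3	1.0513	0.0013			angiogenesis	MAPK signaling pathway
NTSR1	-1.5401	0.0140	novel_miR_669,novel_miR_676,novel_miR_567	MSTRG.63187.27,MSTRG.71117.21,MSTRG.133793.2,MSTRG.29590.15,MSTRG.52146.15,MSTRG.72741.32,MSTRG.148631.1	angiogenesis	Regulation of respiratory gaseous exchange, Calcium signaling pathway
SSTR5	-3.8881	0.0054	novel_miR_819	MSTRG.25881.3	energy metabolism	Glucose homeostasis
NR1H4	-1.1224	0.0179	novel_miR_676	MSTRG.99917.37,MSTRG.64717.15,MSTRG.99917.39,MSTRG.99917.35	energy metabolism	Glucose homeostasis, response to oxygen-containing compound
HTR2C	-1.3476	0.0000			energy metabolism	Regulation of lipid metabolic process
APOA1	1.1034	0.0068			energy metabolism	Regulation of lipid metabolic process
KCNB1	-1.1800	0.0000			energy metabolism	Glucose homeostasis, response to oxygen-containing compound
P3H2	-1.0044	0.0135			energy metabolism	Carbohydrate binding
CHST8	-1.9553	0.0013	novel_miR_693,novel_miR_775		energy metabolism	Carbohydrate metabolic process
LYZ	-1.0365	0.0050			energy metabolism	Carbohydrate metabolic process
HAO2	-1.5483	0.0085	novel_miR_669		energy metabolism	Carbon metabolism, lactate oxidation
ACER1	1.5111	0.0032			energy metabolism	Regulation of lipid metabolic process
ACSBG1	1.1154	0.0000			energy metabolism	Fatty acid metabolism
ELOVL2	-5.1386	0.0480			energy metabolism	Fatty acid metabolism
ELOVL3	2.0872	0.0146	novel_miR_867		energy metabolism	Fatty acid metabolism
GBE	-1.0082	0.0072	novel_miR_85	MSTRG.128588.4	energy metabolism	Oxygen transport, oxygen binding, reactive oxygen species metabolic process
NOX3	3.0828	0.0000			energy metabolism	Reactive oxygen species metabolic process
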