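Entry	Entry name	Protein names	Unique peptides	Sequence coverage [%]	Molecular weight [kDa]	Ratio CB2/ctrl
P34972	CNR2_HUMAN	Cannabinoid receptor 2	16	39.2	39.68	845.0
Q15392	DHC24_HUMAN	Delta(24)-sterol reductase	2	5.4	60.101	Only in CB2
Q9Y394	DHRS7_HUMAN	Dehydrogenase/reductase SDR family member 7	2	14.2	38.298	Only in CB2
Q9UJ14	GGT7_HUMAN	Glutathione hydrolase 7	4	11.2	70.466	Only in CB2
Q5T447	HECD3_HUMAN	E3 ubiquitin-protein ligase HECTD3	2	3.8	97.112	Only in CB2
Q8IYS2	K2013_HUMAN	Uncharacterized protein KIAA2013	4	11.1	72.68	Only in CB2
O15162	PLS1_HUMAN	Phospholipid scramblase 1	4	14.8	35.049	Only in CB2
O14967	CLGN_HUMAN	Calmegin	19	45.7	70.038	12388.6
Q06136	KDSR_HUMAN	3-Ketodihydrosphingosine reductase (KDS reductase)	7	32.2	36.187	2214.8
Q96JJ7	TMX3_HUMAN	Protein disulfide-isomerase TMX3	13	39	51.871	551.6
Q99720	SGMR1_HUMAN	Sigma non-opioid intracellular receptor 1	6	40.4	25.127	370.9
P16615	AT2A2_HUMAN	Sarcoplasmic/endoplasmic reticulum calcium ATPase 2 (SERCA2)	44	48.6	114.76	306.2
P27824	CALX_HUMAN	Calnexin (IP90) (Major histocompatibility complex class I antigen-binding protein p88)	38	57.9	67.567	200.4
Q8IWV7	UBR1_HUMAN	E3 ubiquitin-protein ligase UBR1	3	2.8	200.21	170.0
P37268	FDFT_HUMAN	Squalene synthase	8	24.5	48.115	168.0
Q99442	SEC62_HUMAN	Translocation protein SEC62	4	10	45.861	164.7
O43505	B4GA1_HUMAN	Beta-1.4-glucuronyltransferase 1	2	12.8	47.119	161.7
Q9UBV2	SE1L1_HUMAN	Protein sel-1 homolog 1	2	6.2	88.754	124.8
P10586	PTPRF_HUMAN	Receptor-type tyrosine-protein phosphatase F	5	4.5	212.88	88.1
O95260	ATE1_HUMAN	Arginyl-tRNA--protein transferase 1	4	10.2	59.09	87.4
Q96A33	CCD47_HUMAN	Coiled-coil domain-containing protein 47	11	34.4	55.873	85.3
O15269	SPTC1_HUMAN	Serine palmitoyltransferase 1	4	11.8	52.743	77.3
Q4ZIN3	MBRL_HUMAN	Membralin (Transmembrane protein 259)	3	7.3	67.888	62.9
O43149	ZZEF1_HUMAN	Zinc finger ZZ-type and EF-hand domain-containing protein 1	5	2.8	331.07	55.5
Q13501	SQSTM_HUMAN	Sequestosome-1	6	23.4	47.687	52.7
O15258	RER1_HUMAN	Protein RER1	2	15.3	22.958	51.5
Q9H3N1	TMX1_HUMAN	Thioredoxin-related transmembrane protein 1	3	12.9	31.791	42.2
O00264	PGRC1_HUMAN	Membrane-associated progesterone receptor component 1	8	57.4	21.671	40.5
Q15043	S39AE_HUMAN	Zinc transporter ZIP14 (LIV-1 subfamily of ZIP zinc transporter 4)	2	6.7	54.212	31.2
Q8NI60	COQ8A_HUMAN	Atypical kinase COQ8A mitochondrial	3	8.3	71.949	28.5
P55084	ECHB_HUMAN	Trifunctional enzyme subunit beta mitochondrial	15	43.7	51.294	27.8
P42356	PI4KA_HUMAN	Phosphatidylinositol 4-kinase alpha	2	1.6	231.32	26.3
O75915	PRAF3_HUMAN	PRA1 family protein 3 (ADP-ribosylation factor-like protein 6-interacting protein 5)	2	16	21.614	25.6
A1L0T0	ILVBL_HUMAN	Acetolactate synthase-like protein	4	10.9	67.867	23.1
Q9Y4P3	TBL2_HUMAN	Transducin beta-like protein 2	2	5.6	49.797	22.5
O60884	DNJA2_HUMAN	DnaJ homolog subfamily A member 2	2	6.8	45.745	22.2
Q29963	1C06_HUMAN	HLA class I histocompatibility antigen. Cw-6 alpha chain (MHC class I antigen Cw*6)	5	21.9	40.968	21.5
P20020	AT2B1_HUMAN	Plasma membrane calcium-transporting ATPase 1	3	4.2	138.75	21.1
P49755	TMEDA_HUMAN	Transmembrane emp24 domain-containing protein 10	2	12.8	24.976	19.8
P62341	SELT_HUMAN	Thioredoxin reductase-like selenoprotein T (SelT)	2	17.4	22.174	18.8
P50395	GDIB_HUMAN	Rab GDP dissociation inhibitor beta	2	8.5	50.663	17.0
P49411	EFTU_HUMAN	Elongation factor Tu mitochondrial (EF-Tu)	23	61.5	49.541	15.2
Q8IXI1	MIRO2_HUMAN	Mitochondrial Rho GTPase 2 (MIRO-2) (hMiro-2)	2	4.4	68.117	15.2
Q14257	RCN2_HUMAN	Reticulocalbin-2	2	11	36.876	14.6
Q9BQE3	TBA1C_HUMAN	Tubulin alpha-1C chain (Alpha-tubulin 6)	2	76.2	49.895	12.4
Q9BXW9	FACD2_HUMAN	Fanconi anemia group D2 protein (Protein FACD2)	2	2.3	166.46	12.1
P04844	RPN2_HUMAN	Dolichyl-diphosphooligosaccharide--protein glycosyltransferase subunit 2	11	37.9	69.283	12.1
P04843	RPN1_HUMAN	Dolichyl-diphosphooligosaccharide--protein glycosyltransferase subunit 1	19	43	68.569	12.0
P40939	ECHA_HUMAN	Trifunctional enzyme subunit alpha mitochondrial	27	53.1	82.999	12.0
P39656	OST48_HUMAN	Dolichyl-diphosphooligosaccharide--protein glycosyltransferase 48 kDa subunit	11	45.2	50.8	11.9
Q9BVA1	TBB2B_HUMAN	Tubulin beta-2B chain	3	67.2	49.953	11.5
Q9BQB6	VKOR1_HUMAN	Vitamin K epoxide reductase complex subunit 1	2	19	18.234	11.1
P13797	PLST_HUMAN	Plastin-3 (T-plastin)	2	6.3	70.81	11.0
Q9HCU5	PREB_HUMAN	Prolactin regulatory element-binding protein	3	15.1	45.468	10.8
P07237	PDIA1_HUMAN	Protein disulfide-isomerase (PDI)	2	4.3	57.116	10.3
P51648	AL3A2_HUMAN	Fatty aldehyde dehydrogenase	6	14.4	57.669	9.9
P13073	COX41_HUMAN	Cytochrome c oxidase subunit 4 isoform 1 mitochondrial	2	13.6	19.576	9.0
P08195	4F2_HUMAN	4F2 cell-surface antigen heavy chain (4F2hc)	3	7	71.122	9.0
Q15363	TMED2_HUMAN	Transmembrane emp24 domain-containing protein 2 (Membrane protein p24A)	2	10.9	22.761	8.8
P61204	ARF3_HUMAN	ADP-ribosylation factor 3	2	18.2	20.601	8.8
O15173	PGRC2_HUMAN	Membrane-associated progesterone receptor component 2	2	18.8	23.818	7.9
O95831	AIFM1_HUMAN	Apoptosis-inducing factor 1 mitochondrial	5	11.1	66.9	6.8
P00403	COX2_HUMAN	Cytochrome c oxidase subunit 2	3	16.3	25.565	6.1
P05109	S10A8_HUMAN	Protein S100-A8 (Calgranulin-A)	3	32.3	10.834	6.0
Q12931	TRAP1_HUMAN	Heat shock protein 75 kDa mitochondrial (HSP 75) (TNFR-associated protein 1)	7	13.2	80.109	5.5
P22102	PUR2_HUMAN	Trifunctional purine biosynthetic protein adenosine-3	4	7.5	107.77	5.4
O14975	S27A2_HUMAN	Very long-chain acyl-CoA synthetase (VLACS) (VLCS)	2	5.5	70.311	5.2
P11586	C1TC_HUMAN	C-1-Tetrahydrofolate synthase cytoplasmic (C1-THF synthase)	2	2.7	101.56	5.1
O75396	SC22B_HUMAN	Vesicle-trafficking protein SEC22b (ER-Golgi SNARE of 24 kDa)	2	10.2	24.593	5.1
P30101	PDIA3_HUMAN	Protein disulfide-isomerase A3	5	13.9	56.782	5.1
P53618	COPB_HUMAN	Coatomer subunit beta (Beta-coat protein)	2	2.2	107.14	4.9
P51571	SSRD_HUMAN	Translocon-associated protein subunit delta (TRAP-delta)	2	18.5	18.998	4.8
P61619	S61A1_HUMAN	Protein transport protein Sec61 subunit alpha isoform 1 (Sec61 alpha-1)	2	9	52.264	4.6
P30048	PRDX3_HUMAN	Thioredoxin-dependent peroxide reductase mitochondrial	2	9.8	27.692	4.5
Q7Z6Z7	HUWE1_HUMAN	E3 ubiquitin-protein ligase HUWE1	2	0.5	481.89	4.3
P50402	EMD_HUMAN	Emerin	3	17.3	28.994	4.3
P24534	EF1B_HUMAN	Elongation factor 1-beta (EF-1-beta)	3	26.7	24.763	4.1
Q53GQ0	DHB12_HUMAN	Very-long-chain 3-oxoacyl-CoA reductase	4	21.2	34.324	4.0
Q9P035	HACD3_HUMAN	Very-long-chain (3R)-3-hydroxyacyl-CoA dehydratase 3	9	33.1	43.159	3.8
Q00325	MPCP_HUMAN	Phosphate carrier protein mitochondrial (Phosphate transport protein) (PTP)	8	28.5	39.958	3.7
O14980	XPO1_HUMAN	Exportin-1	5	8.3	123.38	3.7
P06702	S10A9_HUMAN	Protein S100-A9 (Calgranulin-B)	3	36	13.242	3.7
Q86VU5	CMTD1_HUMAN	Catechol O-methyltransferase domain-containing protein 1	4	25.2	28.808	3.6
Q93008	USP9X_HUMAN	Probable ubiquitin carboxyl-terminal hydrolase FAF-X	3	1.7	292.28	3.6
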