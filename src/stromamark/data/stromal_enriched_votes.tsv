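accession	gene	name	unused_score	cov95_percent	peptides95	average_fc	n_up	n_down	n_total
P02462	COL4A1	Collagen alpha-1(IV) chain	17.7	10.5	13	10.1	21	-	26
P05997	COL5A2	Collagen alpha-2(V) chain	50.2	29.9	37	30.5	19	-	23
P07942	LAMB1	Laminin subunit beta-1	81.8	28.3	50	22.2	16	-	27
P12111	COL6A3	Collagen alpha-3(VI) chain	188.9	40.0	116	26.9	19	-	26
P35442	THBS2	Thrombospondin-2	4.4	5.5	6	8.7	19	-	26
Q02809	PLOD1	Procollagen-lysine,2-oxoglutarate 5-dioxygenase 1	37.1	37.5	23	3.3	19	1	24
Q15084	PDIA6	Protein disulfide-isomerase A6	16.1	26.8	9	4.4	20	-	23
Q16610	ECM1	Extracellular matrix protein 1	24.6	30.7	17	10.7	17	-	25
Q96AY3	FKBP10	Peptidyl-prolyl cis-trans isomerase FKBP10	24.3	31.3	14	12.1	15	-	24
Q96CG8	CTHRC1	Collagen triple helix repeat-containing protein 1	4.5	11.5	3	6.3	20	1	23
Q99715	COL12A1	Collagen alpha-1(XII) chain	142.8	35.1	85	17.0	22	1	23
Q9BUD6	SPON2	Spondin-2	26.5	58.3	17	9.8	20	-	24
Q9Y240	CLEC11A	C-type lectin domain family 11 member A	14.6	26.0	7	4.3	15	-	23
P00749	PLAU	Urokinase-type plasminogen activator	12.8	25.1	10	13.9	23	-	25
P01033	TIMP1	Metalloproteinase inhibitor 1	55.9	72.0	80	6.0	24	-	25
P08254	MMP3	Stromelysin-1	28.7	29.1	16	8.2	24	-	24
P67936	TPM4	Tropomyosin alpha-4 chain	12.2	31.0	12	11.1	23	-	27
Q13162	PRDX4	Peroxiredoxin-4	4.0	13.3	4	2.2	24	-	26
Q15121	PEA15	Astrocytic phosphoprotein PEA-15	10.0	62.3	5	4.5	23	1	27
Q15582	TGFBI	Transforming growth factor-beta-induced protein ig-h3	51.1	51.4	52	13.0	24	-	26
O00469	PLOD2	Procollagen-lysine,2-oxoglutarate 5-dioxygenase 2	16.3	20.4	13	6.2	-	15	25
P01023	A2M	Alpha-2-macroglobulin	35.5	21.4	25	3.1	1	26	27
P55083	MFAP4	Microfibril-associated glycoprotein 4	6.0	13.7	3	5.1	-	18	25
Q10588	BST1	ADP-ribosyl cyclase/cyclic ADP-ribose hydrolase 2	3.9	7.5	2	8.7	-	20	26
Q14019	COTL1	Coactosin-like protein	9.1	26.8	6	4.0	1	15	24
Q14315	FLNC	Filamin-C	79.4	24.5	49	18.1	1	15	24
Q16394	EXT1	Exostosin-1	14.6	14.3	10	4.7	-	23	25
Q9UBX5	FBLN5	Fibulin-5	13.0	18.8	7	8.9	1	16	24
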