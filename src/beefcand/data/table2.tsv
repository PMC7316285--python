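gene_id	full_name	symbol	chromosome	start	end	log2fc	pvalue
ENSBTAG00000000448	3-hydroxybutyrate dehydrogenase 1	BDH1	1	72572941	72608810	1.8192	6.45E-04
ENSBTAG00000002151	ankyrin repeat and SOCS box containing 15	ASB15	4	88697392	88729365	1.7126	6.98E-05
ENSBTAG00000002527	zinc finger SWIM-type containing 4	ZSWIM4	7	12959854	12977638	-1.7474	4.06E-04
ENSBTAG00000003403	peptidyl arginine deiminase 2	PADI2	2	136049644	136103406	1.88	1.06E-05
ENSBTAG00000005847	Rho associated coiled-coil containing protein kinase 2	ROCK2	11	86501577	86583652	-1.534	4.61E-04
ENSBTAG00000005857	solute carrier family 6 member 1	SLC6A1	22	55695783	55714644	1.716	1.53E-04
ENSBTAG00000006754	D-box binding PAR bZIP transcription factor	DBP	18	55722336	55729578	1.4405	4.62E-03
ENSBTAG00000007062	insulin like growth factor binding protein 5	IGFBP5	2	105378991	105397646	2.7936	1.53E-02
ENSBTAG00000007131	glutamate decarboxylase like 1	GADL1	22	5258463	5452369	1.7586	2.44E-02
ENSBTAG00000007635	phospholipase C like 1	PLCL1	2	86718341	87086748	1.4057	9.02E-03
ENSBTAG00000008103	aldehyde dehydrogenase 1 family member A1	ALDH1A1	8	49354207	49408166	1.3273	2.22E-02
ENSBTAG00000008353	cyclin dependent kinase inhibitor 1A	CDKN1A	23	10560499	10568780	-2.2471	6.56E-09
ENSBTAG00000008807	F-box and leucine rich repeat protein 22	FBXL22	10	46461587	46466076	1.8751	3.71E-03
ENSBTAG00000008866	glucosidase alpha, neutral C	GANC	10	37754445	37817713	1.8652	4.84E-05
ENSBTAG00000008940	neuronal pentraxin 1	NPTX1	19	52679104	52685498	-2.0194	4.61E-04
ENSBTAG00000009148	glycoprotein A33	GPA33	3	1726504	1779667	-2.1275	1.30E-02
ENSBTAG00000010389	starch binding domain 1	STBD1	6	92967767	92971371	2.2268	7.38E-09
ENSBTAG00000010419	cytochrome P450 family 2 subfamily R member 1	CYP2R1	15	38420926	38445583	-1.913	9.68E-04
ENSBTAG00000011381	solute carrier family 30 member 3	SLC30A3	11	72364682	72373190	-2.2679	3.70E-04
ENSBTAG00000011548	adenosine monophosphate deaminase 1	AMPD1	3	28756908	28768496	1.8424	6.75E-06
ENSBTAG00000011808	Growth/differentiation factor 8	MSTN	2	6213566	6220196	2.034	2.22E-02
ENSBTAG00000046587	cystatin E/M	CST6	29	44766936	44768173	1.8718	1.13E-02
ENSBTAG00000015018	fibronectin type III and SPRY domain-containing protein 2	FSD2	21	23501906	23537791	1.4181	2.39E-03
ENSBTAG00000015402	protein GREB1	GREB1	11	86199420	86268193	-3.9542	4.65E-15
ENSBTAG00000016269	malic enzyme 2	ME2	24	50870262	50928290	-1.622	4.65E-02
ENSBTAG00000016444	reticulophagy regulator 1	RETREG1	20	56709603	56758641	-1.2271	4.16E-02
ENSBTAG00000017765	glutathione S-transferase M2	GSTM2	3	33824401	33834874	1.6982	8.71E-03
ENSBTAG00000016591	RAB11 family interacting protein 3	RAB11FIP3	25	404964	464143	-1.1768	4.52E-02
ENSBTAG00000016676	phosphotriesterase related	PTER	13	31202455	31278293	1.3723	1.40E-02
ENSBTAG00000018088	SET binding protein 1	SETBP1	24	45025456	45141793	1.4051	1.53E-02
ENSBTAG00000018204	myosin heavy chain 1	MYH1	19	30110728	30134757	1.988	2.52E-04
ENSBTAG00000019065	endonuclease/exonuclease/phosphatase family domain containing 1	EEPD1	4	61354648	61476979	1.2436	4.40E-02
ENSBTAG00000019954	abhydrolase domain containing 2	ABHD2	21	20998719	21106763	-1.6449	2.11E-02
ENSBTAG00000021151	myosin heavy chain 10	MYH10	19	28680825	28800880	-1.1847	4.97E-02
ENSBTAG00000034411	shisa family member 3	SHISA3	6	62877287	62880849	-1.9731	3.54E-02
ENSBTAG00000037794	myosin heavy chain 4	MYH4	19	30080604	30103436	2.2376	2.03E-05
ENSBTAG00000038584	olfactomedin 1	OLFM1	11	106675880	106712955	1.5765	1.91E-02
ENSBTAG00000039574	nephrocan	NEPN	9	33595874	33619430	2.4845	1.53E-04
ENSBTAG00000040126	desmoglein 4	DSG4	24	26038529	26078704	-2.6521	4.61E-04
ENSBTAG00000040398	KIAA1211 ortholog	KIAA1211	6	73368358	73396166	2.0568	1.44E-02
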