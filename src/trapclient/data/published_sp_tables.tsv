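table	protein_id	gene	sequence	kind	tm	nglyc	gp_printed	hph_printed	sec61_affected	validated	ost
1	Q9UM22	EPDR1	MPGRAPLRTVPGALGAWLLGGLWAWTLCGLCSLGAVG	SP	0	1	29.7	0.727	1	0	0
1	Q9H6X2	ANTXR1	MATAERRALGIGFQWLSLATLVLICAG	SP	1	1	15.6	0.262	1	0	0
1	Q8IWB1	ITPRIP	MAMGLFRVCLVVVTA	SP	0	1	6.7	1.951	0	0	0
1	O00622	CYR61	MSSRIARALALVVTLLHLTRLALS	SP	0	0	0	1.017	0	0	0
1	P54802	NAGLU	MEAVAVAAAVGVLLLAGAGGAAG	SP	0	1	21.7	1.461	0	0	0
1	Q9GZX9	TWSG1	MKLHYVAVLTLAILMFLTWLPESLS	SP	0	1	4.0	1.269	0	0	0
1	Q13454	TUSC3	MGARGAPSRRRQAGRRLRYLPTGSFPFLLLLLLLCIQLGGG	SP	1	0	24.4	-0.01	0	0	1
1	Q9Y3A6	TMED5	MGDKIWLPFPVLLLAALPPVLLPGAAG	SP	1	0	29.6	1.074	1	1	0
1	Q9H0U3	MAGT1	MAARWRFWCVSVTMVVALLIVCDVPSASA	SP	1	1	3.5	1.227	0	0	0
1	Q13214	SEMA3B	MGRAGAAAVIPGLALLWAVGLGSA	SP	0	1	25.0	1.106	0	0	0
1	Q9BRR6	ADPGK	MALWRGSAYAGFLALAVGCVFL	SP	0	0	13.6	1.356	1	0	0
1	P02751	FN1	MLRGPGPGLLLLAVQCLGTAVPSTGA	SP	0	1	25.8	0.161	0	0	0
1	P45877	PPIC	MGPGPRLLLPLVLCVGLGALVFSSGAEG	SP	0	1	32.1	1.063	1	1	0
1	Q9UMX5	NENF	MVGPAPRRRLRPLAALALVLALAPGLPTARA	SP	0	0	22.6	0.281	0	0	0
1	O14773	TPP1	MGLQACLLGLFALILSGKCSY	SP	0	1	15.8	1.526	0	0	0
1	P15941	MUC1	MTPGTQSPFFLLLLLTVLTVVTG	SP	1	1	17.4	1.310	1	0	0
1	Q15582	TGFBI	MALFVRLLALALALALGPAATLA	SP	0	0	8.7	1.729	0	0	0
1	O75629	CREG1	MAGLSRGSARALLAALLASTLLALLVSPARG	SP	0	1	12.9	0.880	0	0	0
1	Q9ULF5	SLC39A10	MKVHMHTKFCLICLLTFIFHHCNHC	SP	1	1	0	0.707	1	0	0
1	Q08380	LGALS3BP	MTPPRLFWVWLLVAGTQG	SP	0	1	22.2	0.523	0	0	0
1	P08069	IGF1R	MKSGSGGGSPTSLWGLLFLSAALSLWPTSG	SP	1	1	26.7	0.404	1	0	0
1	P08572	COL4A2	MGRDQRAVAGPALRRWLLLGTVTVGFLAQSVLA	SP	0	1	20.0	-0.04	1	0	0
1	Q8N2U0	TMEM256	MAGPAAAFRRLGALSGAAALGFASYGAHG	SP	1	0	24.1	0.292	1	0	0
1	Q9UBV2	SEL1L	MRVRIGLTLLLCAVLLSLASA	SP	1	1	4.8	1.651	1	0	0
1	Q969V3	NCLN	MLEEAGEVLENMLKASCLPLGFIVFLPAVLLLVAPPLPAADA	SP	1	1	16.7	1.038	0	0	0
1	O14672	ADAM10	MVLLRVLILLLSWAAGMG	SP	1	1	15.8	1.775	1	0	0
1	P11117	ACP2	MAGKRSGWSRAALLQLLLGVNLVVMPPTRA	SP	1	1	16.7	0.304	1	1	0
1	P06756	ITGAV	MAFPPRRRLRLGPRGLPLLLSGLLLPLCRA	SP	1	1	29.7	0.163	1	0	0
1	Q12907	LMAN2	MAAEGWIWRWGWGRRCLGRPGLLGPGPGPTTPLFLLLLLGSVTA	SP	1	1	31.8	0.230	0	0	0
1	P56937	HSD17B7	MRKVVLITGASSGIGLALCKRL	SP	1	1	19.1	1.733	0	0	0
1	P39656	DDOST	MGYFRCARAGSFGRRRKMEPSTAARAWALFWLLLPLLGAVCA	SP	1	0	14.3	0.115	1	1	1
1	Q8TB61	SLC35B2	MDARWWAVVVLAAFPSLGAG	SP	1	0	23.8	0.627	0	0	0
1	Q6PIU2	NCEH1	MRSSCVLLTALVALA	SP	0	1	14.3	1.617	0	0	0
1	Q5JPE7	NOMO2	MLVGQGAGLLGPAVVTAAVVLLLSGVGPAHG	SP	1	1	29.0	1.259	0	0	0
1	P08236	GUSB	MARGSAVAWAALGPLLWGCALG	SP	0	1	22.7	0.883	0	0	0
1	P00533	EGFR	MRPSGTAGAALLALLAALCPASRA	SP	1	1	16.7	0.634	1	0	0
1	Q5VW38	GPR107	MAALAPVGSPASRGPRLAAGLRLLPMLGLLQLLAEPGLG	SP	0	1	28.2	0.538	0	0	0
1	Q8N129	CNPY4	MGPVRLGILLFLFLAVHEAWA	SP	0	0	14.3	1.312	1	0	0
3	Q9H173	SIL1	MAPQSLPSSRMAPLGMLLGLLMAACFTFCLS	SP	0	1	16.1	0.992	1	1	0
3	P27797	CALR	MLLSVPLLLGLLGLAVA	SP	0	1	17.6	2.307	1	1	0
3	P14625	HSP90B1	MRALWVLGLCCVLLTFGSVRA	SP	0	1	9.52	1.446	1	0	0
3	Q9Y4L1	HYOU1	MADKVRRQRPRRRVCWALVAVLLADLLALSDT	SP	0	1	3.12	-0.101	1	0	0
3	P23284	PPIB	MLRLSERNMKVLLAAALIAGSVFFLLLPGPSAA	SP	0	1	12.1	0.961	1	0	0
3	-	mut-PPIB	MLRLGPRNMKVLLPPALIAGSVFFLLLPGPSAA	SP	0	1	24.2	0.814	0	0	0
3	Q9Y3A6	TMED5	MGDKIWLPFPVLLLAALPPVLLPGAAG	SP	1	0	29.6	1.074	1	1	0
3	-	mut-TMED5	MGDKIWLPFPVLLLAALPPVLLAAAAG	SP	1	0	22.2	1.250	0	0	0
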