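library	method	tissue	origin	vector	ests_in_contigs	ests_in_singlets	ests_total	clones_sequenced	clones_mapped	loci
ADR01	Oligo-capping	Adrenal gland	LWD (LWD2)	pCMVFL3	6490	3188	9678	901	861	782
AMP01	SMART	Alveolar macrophage	LWD (LWD7)	pDNR-LIB	5459	3704	9163	1416	1345	930
BFLT1	Oligo-capping	Brain (frontal lobe)	Duroc (2-14C)	pME18S	8104	5678	13782	991	953	859
BKFL1	SMART	Backfat	Landrace (L2)	pDNR-LIB	1557	7920	9477	453	418	404
BMWN1	Vector-capping	Bone marrow	NIBS miniature	pGCAP10	5981	2492	8473	148	133	124
CBLT1	Vector-capping	Cerebellum	Duroc (2-14C)	pGCAP10	6082	3054	9136	0	0	0
CLNT1	Oligo-capping	Colon	Duroc (2-14C)	pME18S	6580	6782	13362	537	512	365
DCI01	SMART	Immature dendritic cells	Landrace (L1)	pDNR-LIB	5953	4486	10439	887	841	748
HTMT1	Vector-capping	Hypothalamus	Duroc (2-14C)	pGCAP10	8063	5278	13341	1663	1474	1264
ILNT1	Vector-capping	Inguinal lymph node	Duroc (2-14C)	pGCAP10	6321	2658	8979	0	0	0
ITT01	Oligo-capping	Intestine	LWD (LWD2)	pCMVFL3	7272	2475	9747	1265	1206	1037
KDN01	Oligo-capping	Kidney	LWD (LWD8)	pME18S	5873	3235	9108	748	723	663
LNG01	Oligo-capping	Lung	LWD (LWD3)	pCMVFL3	5186	3859	9045	1331	1250	1061
LVR01	Oligo-capping	Liver	LWD (LWD4)	pCMVFL3	7199	1815	9014	779	741	653
LVRM1	Oligo-capping	Liver	Meishan	pCMVFL3	13881	5051	18932	1844	1760	1372
MLN01	Oligo-capping	Mesenteric lymph node	LWD (LWD2)	pCMVFL3	6443	3250	9693	1176	1099	902
MLTL1	SMART	Longissimus muscle	Landrace (L2)	pDNR-LIB	3577	4892	8469	413	388	292
OVR01	Oligo-capping	Ovary	LWD (LWD1)	pCMVFL3	6537	2828	9365	1416	1356	1226
OVRM1	Oligo-capping	Ovary	Meishan	pCMVFL3	12471	7071	19542	3309	3149	2665
OVRT1	Oligo-capping	Ovary	Duroc (2-14C)	pME18S	9516	4340	13856	819	790	728
PBL01	Oligo-capping	Peripheral blood lymphocytes	LWD (LWD5)	pCMVFL3	6652	3262	9914	957	908	732
PCT01	Oligo-capping	Placenta	LWD (LWD9)	pME18S	2175	1115	3290	161	150	142
PST01	Oligo-capping	Prostate	LWD (LWD10)	pME18S	6813	2329	9142	691	654	596
PTG01	Oligo-capping	Pituitary gland	LWD (LWD4)	pCMVFL3	4281	5628	9909	864	826	790
SKNB1	Oligo-capping	Skin	Berkshire	pME18S	4894	3363	8257	687	630	534
SMG01	Oligo-capping	Submaxillary gland	LWD (LWD2)	pCMVFL3	6944	2680	9624	458	430	361
SPL01	Oligo-capping	Spleen	LWD (LWD1)	pCMVFL3	6793	2811	9604	1457	1397	1207
SPLT1	Vector-capping	Spleen	Duroc (2-14C)	pGCAP10	6037	2734	8771	0	0	0
TCH01	Oligo-capping	Trachea	LWD (LWD3)	pCMVFL3	5151	3658	8809	1412	1345	1087
TES01	Oligo-capping	Testis	LWD (LWD6)	pME18S	7112	2962	10074	697	669	466
THY01	Oligo-capping	Thymus	LWD (LWD1)	pCMVFL3	7586	3704	11290	2158	2066	1620
UTR01	Oligo-capping	Uterus	LWD (LWD1)	pCMVFL3	6796	2626	9422	1441	1356	1180
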