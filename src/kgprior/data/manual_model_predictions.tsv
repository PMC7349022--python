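gene	ensembl_gene	ensembl_transcript	chr	transcript_start	transcript_end	strand	clinvar_genes	clinvar_predictions	disgenet_genes	disgenet_predictions	alsod_genes	alsod_predictions
ALS2	ENSG00000003393	ENST00000489440	2	202581364	202591275	-	TRUE	FALSE	TRUE	FALSE	TRUE	FALSE
BCL2L1	ENSG00000171552	ENST00000307677	20	30252254	30310701	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
BSG	ENSG00000172270	ENST00000573216	19	572571	581376	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
CASP1	ENSG00000137752	ENST00000436863	11	104896234	104905977	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
CHMP2B	ENSG00000083937	ENST00000466696	3	87302198	87303063	+	TRUE	FALSE	TRUE	FALSE	TRUE	FALSE
CLU	ENSG00000120885	ENST00000522413	8	27463898	27472209	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
CNTF	ENSG00000242689	ENST00000361987	11	58390145	58393198	+	TRUE	FALSE	TRUE	FALSE	TRUE	FALSE
CREBBP	ENSG00000005339	ENST00000574740	16	3786508	3794958	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
CST3	ENSG00000101439	ENST00000398409	20	23614293	23619110	-	FALSE	TRUE	TRUE	FALSE	TRUE	FALSE
CTSD	ENSG00000117984	ENST00000438213	11	1775253	1782770	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
DPP6	ENSG00000130226	ENST00000377770	7	153749764	154685161	+	FALSE	TRUE	TRUE	FALSE	TRUE	FALSE
ERBB4	ENSG00000178568	ENST00000484594	2	212426486	213403306	-	TRUE	FALSE	TRUE	FALSE	TRUE	FALSE
FOS	ENSG00000170345	ENST00000556324	14	75745530	75746234	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
GDI1	ENSG00000203879	ENST00000465640	X	153670112	153671075	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
GFAP	ENSG00000131095	ENST00000253408	17	42982993	42992920	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
GLE1	ENSG00000119392	ENST00000309971	9	131266978	131304567	+	FALSE	TRUE	TRUE	FALSE	TRUE	FALSE
GSR	ENSG00000104687	ENST00000221130	8	30535582	30585443	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
GSTP1	ENSG00000084207	ENST00000489040	11	67351604	67352535	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
GSX2	ENSG00000180613	ENST00000326902	4	54966197	54968672	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
HSF1	ENSG00000185122	ENST00000529630	8	145532954	145533780	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
INA	ENSG00000148798	ENST00000369849	10	105036919	105050108	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
JAK3	ENSG00000105639	ENST00000526008	19	17949078	17958841	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
JUND	ENSG00000130522	ENST00000600972	19	18390828	18391739	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
KIF3C	ENSG00000084731	ENST00000455394	2	26149470	26205366	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
LAT	ENSG00000213658	ENST00000566415	16	29000897	29001776	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
LDLR	ENSG00000130164	ENST00000560467	19	11215982	11224300	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
PARK7	ENSG00000116288	ENST00000465354	1	8021807	8031581	+	TRUE	FALSE	TRUE	FALSE	FALSE	FALSE
PLA2G4A	ENSG00000116711	ENST00000466600	1	186823417	186908362	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
PPARGC1A	ENSG00000109819	ENST00000264867	4	23793643	23891700	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
PRPH	ENSG00000135406	ENST00000551194	12	49687034	49687780	+	TRUE	FALSE	TRUE	FALSE	TRUE	FALSE
RXRA	ENSG00000186350	ENST00000484822	9	137208943	137298240	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
SELPLG	ENSG00000110876	ENST00000228463	12	109016604	109025854	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
SHC1	ENSG00000160691	ENST00000448116	1	154934773	154943223	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
SLC1A2	ENSG00000110436	ENST00000531628	11	35287147	35323075	-	FALSE	TRUE	TRUE	FALSE	TRUE	FALSE
SNAI1	ENSG00000124216	ENST00000244050	20	48599535	48605423	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
SOD2	ENSG00000112096	ENST00000541573	6	160103513	160113110	-	FALSE	TRUE	TRUE	FALSE	TRUE	FALSE
TIAM1	ENSG00000156299	ENST00000455508	21	32638611	32716594	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
TLE3	ENSG00000140332	ENST00000557815	15	70341315	70351129	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
TMSB4X	ENSG00000205542	ENST00000451311	X	12993226	12995346	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
TNF	ENSG00000232810	ENST00000449264	6	31543344	31546113	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
TP53	ENSG00000141510	ENST00000574684	17	7577571	7578437	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
TRPM7	ENSG00000092439	ENST00000558444	15	50867155	50874661	-	TRUE	FALSE	TRUE	FALSE	TRUE	FALSE
VIM	ENSG00000026025	ENST00000544301	10	17270257	17279584	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
WNT7A	ENSG00000154764	ENST00000285018	3	13857754	13921618	-	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
XIAP	ENSG00000101966	ENST00000496602	X	123046609	123047465	+	FALSE	TRUE	TRUE	FALSE	FALSE	TRUE
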