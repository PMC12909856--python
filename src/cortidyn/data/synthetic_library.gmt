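PW01	Arginine-like biosynthesis (synthetic)	SMDB0001	SMDB0002	SMDB0003	SMDB0004	SMDB0005	SMDB0006	SMDB0007	SMDB0008	SMDB0009	SMDB0010
PW02	Bile-acid-like biosynthesis (synthetic)	SMDB0011	SMDB0012	SMDB0013	SMDB0014	SMDB0015	SMDB0016	SMDB0017	SMDB0018	SMDB0019	SMDB0020
PW03	Tryptophan-like metabolism (synthetic)	SMDB0021	SMDB0022	SMDB0023	SMDB0024	SMDB0025	SMDB0026	SMDB0027	SMDB0028	SMDB0029	SMDB0030	SMDB0005
PW04	Glycerolipid-like metabolism (synthetic)	SMDB0031	SMDB0032	SMDB0033	SMDB0034	SMDB0035	SMDB0036	SMDB0037	SMDB0038	SMDB0039	SMDB0040
PW05	Alanine-aspartate-glutamate-like metabolism (synthetic)	SMDB0041	SMDB0042	SMDB0043	SMDB0044	SMDB0045	SMDB0046	SMDB0047	SMDB0048	SMDB0003
PW06	Cysteine-methionine-like metabolism (synthetic)	SMDB0049	SMDB0050	SMDB0051	SMDB0052	SMDB0053	SMDB0054	SMDB0055	SMDB0056	SMDB0057	SMDB0058	SMDB0015
PW07	Taurine-like metabolism (synthetic)	SMDB0059	SMDB0060	SMDB0061	SMDB0062	SMDB0063	SMDB0064	SMDB0015	SMDB0050
PW08	Ascorbate-aldarate-like metabolism (synthetic)	SMDB0065	SMDB0066	SMDB0067	SMDB0068	SMDB0069	SMDB0070	SMDB0071	SMDB0072
PW09	TCA-like cycle (synthetic)	SMDB0073	SMDB0074	SMDB0075	SMDB0076	SMDB0077	SMDB0078	SMDB0079	SMDB0080	SMDB0081	SMDB0082	SMDB0045
PW10	Purine-like metabolism (synthetic)	SMDB0083	SMDB0084	SMDB0085	SMDB0086	SMDB0087	SMDB0088	SMDB0089	SMDB0090	SMDB0091	SMDB0092
PW11	Pyrimidine-like metabolism (synthetic)	SMDB0093	SMDB0094	SMDB0095	SMDB0096	SMDB0097	SMDB0098	SMDB0099	SMDB0100
PW12	Sphingolipid-like metabolism (synthetic, edgeless)	SMDB0101	SMDB0102	SMDB0103	SMDB0104	SMDB0105	SMDB0106	SMDB0107	SMDB0108
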