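pathway_id	node_a	node_b
PW01	SMDB0001	SMDB0002
PW01	SMDB0002	SMDB0003
PW01	SMDB0003	SMDB0004
PW01	SMDB0004	SMDB0005
PW01	SMDB0005	SMDB0006
PW01	SMDB0006	SMDB0007
PW01	SMDB0007	SMDB0008
PW01	SMDB0008	SMDB0009
PW01	SMDB0009	SMDB0010
PW02	SMDB0011	SMDB0012
PW02	SMDB0012	SMDB0013
PW02	SMDB0013	SMDB0014
PW02	SMDB0014	SMDB0015
PW02	SMDB0015	SMDB0016
PW02	SMDB0016	SMDB0017
PW02	SMDB0017	SMDB0018
PW02	SMDB0018	SMDB0019
PW02	SMDB0019	SMDB0020
PW03	SMDB0021	SMDB0022
PW03	SMDB0021	SMDB0023
PW03	SMDB0021	SMDB0024
PW03	SMDB0021	SMDB0025
PW03	SMDB0021	SMDB0026
PW03	SMDB0021	SMDB0027
PW03	SMDB0021	SMDB0028
PW03	SMDB0021	SMDB0029
PW03	SMDB0021	SMDB0030
PW03	SMDB0021	SMDB0005
PW04	SMDB0031	SMDB0032
PW04	SMDB0032	SMDB0033
PW04	SMDB0033	SMDB0034
PW04	SMDB0034	SMDB0035
PW04	SMDB0035	SMDB0036
PW04	SMDB0036	SMDB0037
PW04	SMDB0037	SMDB0038
PW04	SMDB0038	SMDB0039
PW04	SMDB0039	SMDB0040
PW04	SMDB0040	SMDB0031
PW05	SMDB0041	SMDB0042
PW05	SMDB0042	SMDB0043
PW05	SMDB0043	SMDB0044
PW05	SMDB0044	SMDB0045
PW05	SMDB0045	SMDB0046
PW05	SMDB0046	SMDB0047
PW05	SMDB0047	SMDB0048
PW05	SMDB0048	SMDB0003
PW06	SMDB0049	SMDB0050
PW06	SMDB0050	SMDB0051
PW06	SMDB0051	SMDB0052
PW06	SMDB0052	SMDB0053
PW06	SMDB0053	SMDB0054
PW06	SMDB0054	SMDB0055
PW06	SMDB0055	SMDB0056
PW06	SMDB0056	SMDB0057
PW06	SMDB0057	SMDB0058
PW06	SMDB0058	SMDB0015
PW07	SMDB0059	SMDB0060
PW07	SMDB0059	SMDB0061
PW07	SMDB0059	SMDB0062
PW07	SMDB0059	SMDB0063
PW07	SMDB0059	SMDB0064
PW07	SMDB0059	SMDB0015
PW07	SMDB0059	SMDB0050
PW08	SMDB0065	SMDB0066
PW08	SMDB0066	SMDB0067
PW08	SMDB0067	SMDB0068
PW08	SMDB0068	SMDB0069
PW08	SMDB0069	SMDB0070
PW08	SMDB0070	SMDB0071
PW08	SMDB0071	SMDB0072
PW09	SMDB0073	SMDB0074
PW09	SMDB0074	SMDB0075
PW09	SMDB0075	SMDB0076
PW09	SMDB0076	SMDB0077
PW09	SMDB0077	SMDB0078
PW09	SMDB0078	SMDB0079
PW09	SMDB0079	SMDB0080
PW09	SMDB0080	SMDB0081
PW09	SMDB0081	SMDB0082
PW09	SMDB0082	SMDB0045
PW09	SMDB0045	SMDB0073
PW10	SMDB0083	SMDB0084
PW10	SMDB0083	SMDB0085
PW10	SMDB0083	SMDB0086
PW10	SMDB0083	SMDB0087
PW10	SMDB0083	SMDB0088
PW10	SMDB0083	SMDB0089
PW10	SMDB0083	SMDB0090
PW10	SMDB0083	SMDB0091
PW10	SMDB0083	SMDB0092
PW11	SMDB0093	SMDB0094
PW11	SMDB0094	SMDB0095
PW11	SMDB0095	SMDB0096
PW11	SMDB0096	SMDB0097
PW11	SMDB0097	SMDB0098
PW11	SMDB0098	SMDB0099
PW11	SMDB0099	SMDB0100
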