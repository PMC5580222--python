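gene	direction	fc_tumor_vs_normal	fdr_tumor_vs_normal	fc_rr_vs_rs	fdr_rr_vs_rs	hr	p_value
CSTF3	UP	1.179	0.0025	1.6031	0.0232	1.7458	0.0300
ST3GAL5	UP	1.6115	0.0083	1.9865	0.0343	1.3127	0.0495
UFD1L	UP	1.3426	<0.0001	1.45	0.0327	1.6790	0.0205
CCDC60	DN	-6.5001	<0.0001	-1.3095	0.0258	0.7688	0.0244
FAM81A	DN	-2.0136	0.0003	-1.7879	0.0473	0.7772	0.0288
FGD2	DN	-1.6559	0.0023	-1.7021	0.0464	0.7755	0.0198
HS3ST6	DN	-2.9678	0.0140	-1.3122	0.044	0.8869	0.0210
ITGB7	DN	-1.3982	0.0169	-2.5899	0.0448	0.7115	0.0050
PRR15L	DN	-6.0454	<0.0001	-2.29	0.0004	0.8618	0.0362
SCGB2A1	DN	-5.769	0.0001	-1.4528	0.0369	0.7743	0.0490
SCNN1A	DN	-4.9431	<0.0001	-4.8042	0.033	0.8432	0.0215
ST6GALNAC1	DN	-6.5319	<0.0001	-3.2498	0.0011	0.8826	0.0436
VILL	DN	-1.8517	0.0077	-2.9028	0.0055	0.7511	0.0337
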