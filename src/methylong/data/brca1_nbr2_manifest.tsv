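# BRCA1/NBR2 bidirectional promoter candidate CpGs (Illumina MethylationEPIC v2.0 annotations)
# Coordinates: hg19 (GRCh37), 1-based inclusive.
probe_id	chromosome	position	regulatory_feature	island_relation	gene
cg08386886	17	41277274	Promoter Associated	N Shore	BRCA1;NBR2
cg24806953	17	41277364	Promoter Associated	N Shore	BRCA1;NBR2
cg20187250	17	41277381	Promoter Associated	N Shore	BRCA1;NBR2
cg15419295	17	41277389	Promoter Associated	N Shore	BRCA1;NBR2
cg16963062	17	41277392	Promoter Associated	N Shore	BRCA1;NBR2
cg16630982	17	41277394	Promoter Associated	N Shore	BRCA1;NBR2
cg21253966	17	41277426	Promoter Associated	N Shore	BRCA1;NBR2
cg04110421	17	41277428	Promoter Associated	N Shore	BRCA1;NBR2
cg04658354	17	41277444	Promoter Associated	N Shore	BRCA1;NBR2
cg17301289	17	41277462	Promoter Associated	N Shore	BRCA1;NBR2
cg09441966	17	41277487	Promoter Associated	N Shore	BRCA1;NBR2
cg26891576	17	41277541	Promoter Associated	N Shore	BRCA1;NBR2
cg10893007	17	41277694	Promoter Associated	N Shore	BRCA1;NBR2
cg12182452	17	41277730	Promoter Associated	N Shore	BRCA1;NBR2
cg09831010	17	41277847	Promoter Associated	N Shore	BRCA1
cg25067162	17	41277974	Promoter Associated	N Shore	BRCA1
cg26276233	17	41278135	NA	Island	BRCA1
cg06001716	17	41278141	NA	Island	BRCA1
cg02286533	17	41278179	NA	Island	BRCA1
cg14947218	17	41278197	NA	Island	BRCA1
cg16006004	17	41278241	NA	Island	BRCA1
cg18372208	17	41278263	NA	Island	BRCA1
cg14687474	17	41278281	NA	Island	BRCA1
cg25288140	17	41278341	NA	Island	BRCA1
cg27581762	17	41278563	NA	S Shore	BRCA1
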