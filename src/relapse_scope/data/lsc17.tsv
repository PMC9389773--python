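gene	weight
DNMT3B	0.0874
ZBTB46	-0.0347
NYNRIN	0.00865
ARHGAP22	-0.0138
LAPTM4B	0.00582
MMRN1	0.0258
DPYSL3	0.0284
KIAA0125	0.0196
CDK6	-0.0704
CPXM1	-0.0258
SOCS2	0.0271
SMIM24	-0.0226
EMP1	0.0146
NGFRAP1	0.0465
CD34	0.0338
AKR1C3	-0.0402
GPR56	0.0501
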