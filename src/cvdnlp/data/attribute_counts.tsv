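category	before	during	after	continuing	total
O2	0	0	0	18	18
Hypertension	405	1909	10	1405	3729
Diabetes	-	-	-	-	1007
Dyslipidemia	4	287	6	75	372
CKD	0	0	0	26	26
Atherosis	3	4	0	137	144
OSAS	0	0	0	1	1
Smoking	8	0	0	500	508
A2	9	0	0	86	95
FHCVD	0	0	0	10	10
Age	-	-	-	-	1859
Gender	-	-	-	-	1909
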