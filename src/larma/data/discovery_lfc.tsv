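gene	GDS1962:astrocytoma_gII	GDS1962:astrocytoma_gIII	GDS1962:glioblastoma_gIV	GDS1962:oligodendroglioma_gII	GDS1962:oligodendroglioma_gIII	GDS3592:ovarian_cancer
OIP5-AS1	-1	-1.3	-1.5	-1	-1.5	-1.3
RFPL1S	-2.5	-2.6	-3.8	-2.3	-3.3	-2.5
MEG3	-2.4	-2.8	-2.7	-2.6	-2.7	1.2
KRTAP5-AS1	-1.7	-1.7	-2	-1.1	-1.8	1
LINC00301	-2.2	-1.5	-1.9	-1.4	-2.1	1.9
PART1	-1.4	-1.7	-2	-1.4	-1.9	2.4
PPP1R26-AS1	-1.4	-1.4	-1.2	-1.1	-1.4	1.9
SYN2	-2.6	-2.6	-4	-2.5	-3.8	2.2
CRNDE	3.2	3.6	4.2	1.8	3.7	-4.3
RUSC1-AS1	1.6	1.5	1.2	1.4	1.5	2
UBL7-AS1	1.8	1.6	1.5	1.4	1.8	1.6
DLEU2	1	1	1.5	1	1.4	1.5
UHRF1	2.5	3.6	4	3.1	3.8	3.4
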