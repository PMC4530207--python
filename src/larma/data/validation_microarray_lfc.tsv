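gene	E-GEOD-16011:astrocytoma_gII	E-GEOD-16011:astrocytoma_gIII	E-GEOD-16011:glioblastoma_gIV	E-GEOD-16011:oligodendroglioma_gII	E-GEOD-16011:oligodendroglioma_gIII
OIP5-AS1	-1.0	-1.5	-1.8	-1.0	-1.5
RFPL1S	-3.8	-4.6	-4.8	-3.1	-3.6
MEG3	-2.7	-3.8	-3.7	-2.7	-3.7
KRTAP5-AS1	-1.0	-1.1	-1.1	-1.0	-1.0
LINC00301	-0.3	-0.3	-0.3	-0.3	-0.3
PART1	-2.9	-3.4	-3.3	-3.1	-3.3
PPP1R26-AS1	-0.3	-0.4	-0.2	-0.3	-0.3
SYN2	-3.8	-5.4	-5.4	-3.9	-5.1
CRNDE	2.8	3.7	4.4	n.s.	2.8
RUSC1-AS1	n.s.	0.8	n.s.	1.0	1.1
UBL7-AS1	0.5	0.9	0.8	0.7	0.8
DLEU2	1.4	1.9	1.4	1.6	1.8
UHRF1	2.9	3.2	3.6	3.7	3.4
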