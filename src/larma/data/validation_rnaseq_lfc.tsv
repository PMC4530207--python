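gene	SRP027383:astrocytoma	SRP027383:glioblastoma	SRP027383:oligodendroglioma
OIP5-AS1	-0.3	-0.3	-0.4
RFPL1S	-2.2	-4.7	-1.7
MEG3	n.s.	0.6	-2.0
KRTAP5-AS1	-3.0	-3.2	-1.4
LINC00301	n.s.	n.s.	n.s.
PART1	-3.0	-4.2	-1.0
PPP1R26-AS1	n.s.	n.s.	n.s.
SYN2	-2.5	-2.2	-3.8
CRNDE	4.7	4.7	4.9
RUSC1-AS1	1.5	n.s.	1.0
UBL7-AS1	2.0	1.8	2.3
DLEU2	2.3	2.1	4.0
UHRF1	2.5	1.8	2.5
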