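measure	group	mean	sd	n
Age	SDS	11.35	1.87	5
Age	control	10.82	2.16	5
VC	SDS	85.6	17.9	5
VC	control	109.8	8.49	5
WM	SDS	96.6	20	5
WM	control	110.6	13.27	5
FR	SDS	87.2	19.56	5
FR	control	103	11.02	5
VS	SDS	83.8	15.59	5
VS	control	114.2	4.88	5
PS	SDS	100.8	23.62	5
PS	control	101.2	9.83	5
GAI	SDS	85.53	16.51	5
GAI	control	109	9.21	5
CPI	SDS	98.7	20.75	5
CPI	control	105.9	12.08	5
IQ	SDS	83.4	18.83	5
IQ	control	109.8	12.02	5
ER	SDS	8.75	2.86	5
ER	control	10	3.57	5
ToM-V	SDS	5.4	6.39	5
ToM-V	control	64	30.07	5
ToM-C	SDS	5.8	6.67	5
ToM-C	control	55	31.56	5
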