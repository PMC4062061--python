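row	union_count	count_a	count_b	match_count	category_match_count	rate_a	rate_b	overall_category_rate	overall_rate
LOF_total	104915	77527	96761	68284	69373	88.08	70.57	66.12	65.09
Frameshift	19021	15822	16685	13486	-	85.24	80.83	-	70.90
Stop_gained	16758	14960	16146	14348	-	95.91	88.86	-	85.62
Stop_lost	1113	906	1077	870	-	96.03	80.78	-	78.17
All_splicing	69112	45839	62853	39580	-	86.35	62.97	-	57.27
MISSENSE_total	350806	324242	347752	318056	321188	98.09	91.46	91.56	90.66
Inframe_indel	9455	8650	6600	5795	-	66.99	87.80	-	61.29
Missense	343284	315592	339953	312261	-	98.94	91.85	-	90.96
Initiator_codon	1199	0	1199	0	-	-	0.00	-	0.00
SYNONYMOUS_OTHER_total	182120	172463	175483	165643	165826	96.05	94.39	91.05	90.95
Synonymous	181873	172463	175053	165643	-	96.05	94.62	-	91.08
Stop_retained	203	0	203	0	-	-	0.00	-	0.00
Other_coding	227	0	227	0	-	-	0.00	-	0.00
ALL_LOF	104915	77527	96761	68284	69373	88.08	70.57	66.12	65.09
ALL_LOF_AND_MISSENSE	455721	401769	444513	386340	390561	96.16	86.91	85.70	84.78
ALL_EXONIC	637841	574232	619996	551983	556387	96.13	89.03	87.23	86.54
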