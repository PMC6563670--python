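# Genome-wide pooled codon usage of Beauveria bassiana (10,363 nuclear CDS,
# assembly ASM28067v1), transcribed from the published genome-wide
# codon-usage study of that assembly.  printed_rscu is the RSCU value the
# study prints next to each total count (1 d.p. where it prints 1 d.p.).
codon	count	printed_rscu
UUU	97124	1.04
UUC	90092	0.96
UUA	15257	0.2
UUG	61046	0.8
CUU	69405	0.91
CUC	150168	1.96
CUA	36366	0.47
CUG	127510	1.66
AUU	100384	1.25
AUC	112518	1.41
AUA	27324	0.34
AUG	115524	1
GUU	63597	0.8
GUC	143919	1.8
GUA	28295	0.35
GUG	83697	1.05
UAU	44250	0.64
UAC	93320	1.36
UGU	17074	0.51
UGC	49552	1.49
CAU	45803	0.73
CAC	80397	1.27
CAA	77403	0.73
CAG	133706	1.27
AAU	66104	0.73
AAC	115356	1.27
AAA	68568	0.57
AAG	173994	1.43
GAU	112138	0.74
GAC	192144	1.26
GAA	110930	0.73
GAG	193581	1.27
UCU	63684	0.92
UCC	81713	1.18
UCA	44120	0.64
UCG	84448	1.22
AGU	34859	0.5
AGC	106765	1.54
CCU	64901	0.86
CCC	98366	1.3
CCA	56636	0.75
CCG	82011	1.09
ACU	56368	0.74
ACC	99999	1.31
ACA	58385	0.77
ACG	89814	1.18
GCU	101796	0.82
GCC	202360	1.63
GCA	76891	0.62
GCG	116536	0.94
UGG	74428	1
CGU	44390	0.82
CGC	125865	2.33
CGA	47855	0.89
CGG	40937	0.76
AGA	36237	0.67
AGG	29101	0.54
GGU	72400	0.81
GGC	192920	2.16
GGA	52839	0.59
GGG	39116	0.44
UGA	3421	0.99
UAA	3595	1.04
UAG	3348	0.97
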