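# Escherichia coli K-12 genome-wide codon usage, per-1000-codon frequencies
# (Kazusa codon-usage compilation for E. coli K-12 MG1655 CDSs, rounded to
# one decimal). Weights are proportional frequencies; only the ratio within
# each amino acid matters for weighted-random reverse translation.
# columns: aa<TAB>codon<TAB>weight
F	TTT	22.2
F	TTC	16.6
L	TTA	13.9
L	TTG	13.7
L	CTT	11.0
L	CTC	11.0
L	CTA	3.9
L	CTG	52.6
I	ATT	30.3
I	ATC	25.1
I	ATA	4.4
M	ATG	27.9
V	GTT	18.3
V	GTC	15.3
V	GTA	10.9
V	GTG	26.4
S	TCT	8.5
S	TCC	8.6
S	TCA	7.2
S	TCG	8.9
S	AGT	8.8
S	AGC	16.1
P	CCT	7.0
P	CCC	5.5
P	CCA	8.4
P	CCG	23.2
T	ACT	9.0
T	ACC	23.4
T	ACA	7.1
T	ACG	14.4
A	GCT	15.3
A	GCC	25.5
A	GCA	20.1
A	GCG	33.6
Y	TAT	16.2
Y	TAC	12.2
*	TAA	2.0
*	TAG	0.2
*	TGA	0.9
H	CAT	12.9
H	CAC	9.7
Q	CAA	15.3
Q	CAG	28.8
N	AAT	17.7
N	AAC	21.7
K	AAA	33.6
K	AAG	10.3
D	GAT	32.1
D	GAC	19.1
E	GAA	39.4
E	GAG	17.8
C	TGT	5.2
C	TGC	6.4
W	TGG	15.2
R	CGT	20.9
R	CGC	22.0
R	CGA	3.6
R	CGG	5.4
R	AGA	2.1
R	AGG	1.2
G	GGT	24.7
G	GGC	29.6
G	GGA	8.0
G	GGG	11.1
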