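# Per-codon counts for the human vitamin D-binding protein (VDBP) CDS, NM_000583.3.
# Sense codons of the 18 multi-codon amino acids only (ATG/TGG/stops omitted).
codon	count
TTT	11
TTC	8
TTA	5
TTG	6
CTT	11
CTC	9
CTA	10
CTG	16
ATT	3
ATC	3
ATA	2
GTT	6
GTC	8
GTA	7
GTG	6
TCT	10
TCC	9
TCA	12
TCG	0
CCT	9
CCC	6
CCA	10
CCG	1
ACT	10
ACC	11
ACA	9
ACG	2
GCT	15
GCC	9
GCA	7
GCG	2
TAT	9
TAC	7
CAT	4
CAC	4
CAA	8
CAG	4
AAT	12
AAC	6
AAA	20
AAG	23
GAT	16
GAC	10
GAA	27
GAG	16
TGT	14
TGC	14
CGT	0
CGC	0
CGA	2
CGG	1
AGT	6
AGC	5
AGA	5
AGG	5
GGT	1
GGC	5
GGA	5
GGG	3
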