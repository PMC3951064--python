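# Per-codon counts for the human serum albumin (ALB) CDS, NM_000477.5.
# Sense codons of the 18 multi-codon amino acids only (ATG/TGG/stops omitted).
codon	count
TTT	25
TTC	10
TTA	10
TTG	12
CTT	19
CTC	7
CTA	4
CTG	12
ATT	4
ATC	4
ATA	1
GTT	12
GTC	7
GTA	8
GTG	16
TCT	3
TCC	7
TCA	6
TCG	3
CCT	10
CCC	6
CCA	7
CCG	1
ACT	7
ACC	9
ACA	11
ACG	2
GCT	30
GCC	14
GCA	17
GCG	2
TAT	13
TAC	6
CAT	11
CAC	5
CAA	11
CAG	9
AAT	11
AAC	6
AAA	40
AAG	20
GAT	25
GAC	11
GAA	38
GAG	24
TGT	15
TGC	20
CGT	3
CGC	1
CGA	3
CGG	2
AGT	6
AGC	3
AGA	13
AGG	5
GGT	3
GGC	3
GGA	6
GGG	1
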