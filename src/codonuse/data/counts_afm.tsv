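# Per-codon counts for the human afamin (AFM) CDS, NM_001133.2.
# Sense codons of the 18 multi-codon amino acids only (ATG/TGG/stops omitted).
codon	count
TTT	28
TTC	15
TTA	11
TTG	8
CTT	11
CTC	9
CTA	6
CTG	10
ATT	10
ATC	7
ATA	11
GTT	13
GTC	6
GTA	6
GTG	11
TCT	12
TCC	5
TCA	6
TCG	0
CCT	12
CCC	5
CCA	11
CCG	0
ACT	10
ACC	7
ACA	13
ACG	4
GCT	11
GCC	5
GCA	9
GCG	3
TAT	9
TAC	8
CAT	8
CAC	5
CAA	17
CAG	10
AAT	17
AAC	16
AAA	28
AAG	14
GAT	15
GAC	8
GAA	40
GAG	19
TGT	13
TGC	19
CGT	2
CGC	1
CGA	2
CGG	0
AGT	5
AGC	9
AGA	12
AGG	5
GGT	4
GGC	5
GGA	13
GGG	4
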