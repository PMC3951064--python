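# Per-codon counts for the human alpha-fetoprotein (AFP) CDS, NM_001134.1.
# Sense codons of the 18 multi-codon amino acids only (ATG/TGG/stops omitted).
codon	count
TTT	17
TTC	15
TTA	10
TTG	11
CTT	9
CTC	4
CTA	9
CTG	17
ATT	15
ATC	8
ATA	11
GTT	11
GTC	6
GTA	6
GTG	7
TCT	8
TCC	3
TCA	10
TCG	3
CCT	9
CCC	4
CCA	8
CCG	0
ACT	16
ACC	6
ACA	12
ACG	2
GCT	15
GCC	11
GCA	21
GCG	3
TAT	9
TAC	8
CAT	13
CAC	3
CAA	23
CAG	17
AAT	10
AAC	10
AAA	33
AAG	18
GAT	21
GAC	12
GAA	34
GAG	21
TGT	18
TGC	16
CGT	2
CGC	1
CGA	2
CGG	1
AGT	9
AGC	3
AGA	11
AGG	7
GGT	3
GGC	3
GGA	6
GGG	4
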