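# codonuse

Synonymous codon usage bias analysis for coding sequences, built around
the human albumin superfamily (serum albumin ALB, α-fetoprotein AFP,
afamin AFM, and vitamin D-binding protein VDBP — the four paralogous
serum transport genes on human chromosome 4).

Most amino acids are encoded by several synonymous codons, and genes use
them unequally. `codonuse` computes the standard descriptive indices of
that bias from a coding sequence (or directly from a per-codon count
table):

- **Codon counts and nucleotide composition** — A/T/G/C counts and AT/GC
  percentages over the full ORF.
- **RSCU** (relative synonymous codon usage) —
  `RSCU_ij = X_ij / ((1/n_i) Σ_j X_ij)`: the observed count of codon *j*
  for amino acid *i* over the count expected under uniform use of its
  `n_i` synonymous codons. 1.0 means no bias; Leu, Ser and Arg are
  normalised jointly over all six of their codons.
- **Effective number of codons** — Wright's
  `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` from per-family homozygosities
  `F = (n Σ p_k² − 1)/(n − 1)`, capped at 61; ranges from 20 (one codon
  per amino acid) to 61 (uniform usage). Alongside it, the
  composition-only expectation `ENC(s) = 2 + s + 29/(s² + (1−s)²)` with
  `s` the synonymous GC3 fraction.
- **GC3s** — the G|C fraction at third positions of synonymous codons
  (Met, Trp and stops excluded).
- **GRAVY** — grand average of hydropathy of the translated product,
  `(1/N) Σ K_i` under the Kyte–Doolittle scale; negative = hydrophilic.
- **Rare codons** — each codon's genomic usage rescaled so the most-used
  codon of its family scores 100; codons under a threshold (default 30)
  are rare, and the per-gene summary is the percentage of rare codons.
- **A+U vs G+C preference** — per family, the RSCU-argmax codon, tallied
  by whether preferred codons end in A/U or G/C.

The per-codon count tables of the four albumin-superfamily CDSs and their
full-ORF nucleotide counts ship as packaged fixtures, so the published
indices can be recomputed without any downloads; a synthetic-CDS
generator with controlled per-family codon probabilities makes every
estimator testable against known truth.

## Worked example

Analyze the four packaged fixtures:

```sh
codonuse analyze --fixtures ALB,AFP,AFM,VDBP --out demo --quiet
cat demo/summary.tsv
```

```text
gene	orf_length_bp	total_codons	gravy	pct_AT	pct_GC	gc3_pct	enc_observed	enc_expected	rare_pct	rare_threshold	preference_scheme	au_count	gc_count	tie_rows
ALB	NA	600	NA	NA	NA	38.00	53.91	57.22	4	30	display_rows	15	3	2
AFP	NA	605	NA	NA	NA	37.02	53.76	56.71	5	30	display_rows	17	1	2
AFM	NA	583	NA	NA	NA	37.39	52.67	56.91	4	30	display_rows	16	2	2
VDBP	NA	465	NA	NA	NA	42.80	56.62	59.25	5	30	display_rows	11	4	5
```

Reading the ALB row: its 600 synonymous codons have GC3 = 38%, so
composition alone would predict ~57.2 effective codons, while the
observed Wright Nc is 53.91 — high (weak bias), but below the
expectation curve. Only 4% of its codons are rare in the human genome
(score < 30), and 15 of 20 amino-acid rows prefer an A/U-ending codon
versus 3 preferring G/C (2 rows tie), the signature of an AT-rich
region rather than translational selection. Columns that need the
actual nucleotide sequence (GRAVY, AT/GC content, ORF length) are `NA`
for count-only fixtures; give FASTA files to fill them:

```sh
codonuse analyze my_transcripts.fasta --format json --out demo
```

which extracts the longest forward-strand ATG…stop ORF of each record,
translates it, and reports all statistics at full precision. The same
pipeline is available as a library:

```python
from codonuse import table3_fixture, enc_observed, rscu

alb = table3_fixture("ALB")
print(round(enc_observed(alb).nc_observed, 2))   # 53.91
print(round(rscu(alb).get("TTT"), 2))            # 1.43  (Phe TTT, 25 of 35)
```

Synthetic sequences with controlled bias come from `codonuse simulate`
(or `codonuse.synthetic.generate_cds`), e.g.
`codonuse simulate --n-codons 1000 --seed 7 --bias single-codon` emits a
CDS whose Nc is exactly 20.

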