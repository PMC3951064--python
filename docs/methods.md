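# Methods

## Scope and data model

`codonuse` computes descriptive indices of synonymous codon usage bias.
The unit of analysis is a validated coding sequence (`CodingSequence`):
ATG-initiated, exactly one stop codon and it is terminal, length
divisible by three, DNA alphabet (U normalised to T at input). All
codon-usage statistics operate on the sense codons (terminal stop
excluded); full-ORF nucleotide composition includes the stop codon,
matching the convention under which the packaged per-gene nucleotide
counts sum to the ORF length (e.g. ALB: 556+488+421+365 = 1830 bp).

Statistics can equally be computed from a bare 64-entry codon-count
table, which is how the packaged albumin-superfamily fixtures are
analysed: the published per-codon counts cover the 59 sense codons of
the 18 multi-codon amino acids (ATG and TGG, being non-degenerate, were
not tabulated), so sequence-dependent quantities (composition, GRAVY,
ORF length) are reported as unavailable rather than guessed for
count-only input.

## ORF selection

The ORF rule is: longest forward-strand ATG-initiated frame terminating
in a stop with no internal stop; ties break to the 5'-most start.
Reverse-strand and six-frame search are out of scope. The rule is a
documented assumption — the reference CDSs it must reproduce are all
annotated CDSs that satisfy it — and is property-tested against an
exhaustive O(n²) scan over all substrings. Ambiguity codes (N, R, …)
are rejected with an error listing the offending symbols; silent
skipping would corrupt every downstream count.

## Indices

**RSCU.** For amino acid *i* with `n_i` synonymous codons and counts
`X_ij`, `RSCU_ij = X_ij · n_i / Σ_j X_ij`. Leu, Ser and Arg are single
six-fold families normalised jointly over all six codons (the packaged
ALB Ser values are consistent only with joint normalisation; a 2+4
split would give RSCU(UCC) = 1.47, not the printed 1.50). Amino acids
with zero occurrences yield *undefined* (`None`), not zero. Invariant:
family sums equal the degeneracy for every present amino acid (±1e-9).

**Synonymous GC3.** 100 × (G|C-ending codons of multi-codon amino
acids) / (all codons of multi-codon amino acids). Met, Trp and stop are
excluded from numerator and denominator; for ALB this is 228/600 =
38.00%, whereas an all-codon GC3 would not reproduce the published
value.

**Wright's Nc.** Per family, homozygosity
`F = (n Σ p_k² − 1)/(n − 1)` with `p_k` the within-family codon
proportions and `n` the family total. Class means `F̄_k` are arithmetic
means over the families of each degeneracy class (9 two-fold, Ile the
lone three-fold, 5 four-fold, Leu/Ser/Arg six-fold), and
`Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, capped at 61.0 (near-uniform
small samples can exceed 61 numerically). Families with `n < 2` or
`F ≤ 0` (possible for near-uniform usage at small n) are dropped from
their class mean — the CodonW-style practice. If the three-fold class
is empty, `F̄₃` is imputed as `(F̄₂ + F̄₄)/2`; an empty class of any
other degeneracy raises an error rather than inventing a value. The
packaged gene data never trigger either fallback.

**Expected ENC.** `ENC(s) = 2 + s + 29/(s² + (1−s)²)`, `s` ∈ [0,1] the
GC3 fraction: the Nc a gene would show if third-base composition alone
(mutation pressure and drift) governed codon choice. It is evaluated
exactly, never capped, and reported *alongside* the observed Wright Nc
— the two deliberately differ (ALB: 57.22 expected vs 53.91 observed)
and answer different questions.

**GRAVY.** Mean Kyte–Doolittle hydropathy over the translated product.
The scale is injectable but defaults to Kyte–Doolittle (the ProtParam
convention); the implementation is cross-checked in tests against
Biopython's independent `ProteinAnalysis.gravy`.

**Rare codons.** A reference usage table (any consistent unit) is
rescaled within each synonymous family so the most-used codon scores
100; single-codon families score 100 by definition. A codon scoring
below the threshold (default 30, CLI-overridable) is rare;
the per-gene figure is the percentage of sense codons that are rare,
rounded to whole percent for report output only. The bundled human
reference is the widely reproduced codon-usage-database (Kazusa) tally
of GenBank human CDSs in occurrences per thousand. The published 4/3/4/4%
figures for the superfamily came from a web service whose reference
version is unstated, so they are validated as approximate properties
(±2 percentage points), not exact targets; with the bundled table the
recomputed values are 4–5%.

**Preference tally.** Per row, the preferred codon(s) are the RSCU
argmax. Two row schemes: `amino_acid_families` (18 rows) and
`display_rows` (20 rows, Ser and Arg each split into their four-codon
and two-codon display blocks, argmax taken within each block over the
jointly normalised values). Rows whose preferred set is not a single
codon are excluded from both tallies by default; the published summary
table could not be reproduced exactly under any tie rule we tried (its
own row totals are inconsistent across genes), so the package reports
its own reproducible tally — `ties="same_ending"` optionally keeps tie
rows whose codons all share an ending class. The tally is validated by
equivalence against an exhaustive argmax hand-tally, not against the
published table.

## Synthetic data

`generate_cds` draws interior codons i.i.d. — amino acid from
`aa_probs`, codon from that amino acid's `family_probs` (uniform when
unspecified) — then prepends ATG and appends TAA. The generator is
seeded (NumPy PCG64; the seed is recorded in the identifier and FASTA
header) and vectorised per amino acid. Expected values are analytic:
RSCU of a codon with family probability p is `n_i · p`; one-codon
families drive Nc to 20; uniform usage drives it to 61.

What the generator does *not* emulate: dinucleotide/codon-pair
structure, positional trends along the ORF, amino-acid composition of
real proteins, and isochore/GC gradients. Passing tests therefore
demonstrate estimator correctness under the i.i.d. model, not that real
genes satisfy it; the published-value reproductions run on the real
per-gene counts instead.

Default study conditions in tests: the one-codon-per-family limit uses
2 000 interior codons; the near-uniform limit 50 000 (Nc must land in
[60, 61]); parameter recovery uses Phe-only interiors with codon
probabilities (0.714, 0.286) — the ALB-like Phe bias — at 10 000
codons over 20 seeds, requiring RSCU(UUU) within ±0.05 of 1.43 in at
least 19. All-Phe interiors are used so the full 10 000 codons inform
the estimate; diluting Phe to a realistic amino-acid share would shrink
the Phe sample ~20-fold and turn the ±0.05 band into a ~1σ coin flip.
Generator goodness-of-fit is checked by chi-square on a six-codon
family at α = 0.01 over 20 fixed seeds (≤1 rejection allowed; expected
0.2).

## Numerical conventions

- Published tables round half-up; all comparisons against printed
  values use decimal half-up rounding at the printed precision (RSCU
  and ENC 2 dp, AT/GC 3 dp, per-base composition 1 dp).
- TSV reports use fixed float formatting and fixed row ordering so
  reruns are byte-identical; JSON carries full precision.
- Internal computation is double precision throughout; no index is
  rounded before being consumed by another.

## Known limitations

- Five printed RSCU cells of AFM Ser and seven of AFP Ser/Gly are
  internally inconsistent with their own printed counts (their printed
  family sums violate the sum-equals-degeneracy identity). The fixtures
  carry the counts; the reproduction test documents and tolerates
  exactly those cells.
- Observed Nc recomputed from the printed AFP/AFM counts differs by
  ~1 unit from the published per-gene values (consistent with the count
  transcription errors above); ALB and VDBP reproduce to 2 dp.
- The rare-codon percentages depend on the reference table version;
  only within-family ratios matter, but different tallies shift codons
  across the threshold.
- No CAI/tAI, correspondence analysis, codon optimisation, or
  evolutionary inference: the package computes the descriptive indices
  only.
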