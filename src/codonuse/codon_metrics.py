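"""Core codon-usage statistics.

Implements the descriptive indices of synonymous codon usage bias:

* per-gene codon counts and nucleotide composition;
* synonymous GC3 (G|C fraction at third positions, Met/Trp/stop excluded);
* relative synonymous codon usage,
  ``RSCU_ij = X_ij / ((1/n_i) * sum_j X_ij)``, i.e. the observed count of
  codon *j* for amino acid *i* over the count expected if the *n_i*
  synonymous codons were used uniformly;
* Wright's effective number of codons,
  ``Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``, from mean family homozygosities
  ``F = (n * sum p_k^2 - 1) / (n - 1)`` averaged within each degeneracy
  class, capped at 61;
* the composition-only expectation ``ENC(s) = 2 + s + 29/(s^2 + (1-s)^2)``
  where ``s`` is the GC3 fraction — the Nc a gene would show if third-base
  composition alone (mutation pressure and drift, no selection) set its
  codon usage.

The observed Nc and the GC3-expected ENC answer different questions and
are reported separately: a gene under translational selection sits below
the expectation curve.

Leu, Ser and Arg are handled as single six-fold families throughout
(joint normalisation over all six codons), not as 2+4 splits.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .genetic_code import GC_BASES, GeneticCode, standard_code
from .seqio import CodingSequence

__all__ = [
    "CodonCountTable",
    "CompositionSummary",
    "RSCUTable",
    "ENCResult",
    "count_codons",
    "composition",
    "gc3_synonymous",
    "rscu",
    "enc_observed",
    "enc_expected",
    "UndefinedResultError",
]

NC_MAX = 61.0

#: degeneracy class → number of amino-acid families in the standard code
FAMILIES_PER_CLASS = {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}


class UndefinedResultError(ValueError):
    """A statistic is undefined for the given counts (e.g. empty family class)."""


@dataclass(frozen=True)
class CodonCountTable:
    """64-entry codon→count map for one gene (sense codons; stop excluded)."""

    counts: dict[str, int]
    source_id: str = ""

    def __post_init__(self) -> None:
        bad = {c: n for c, n in self.counts.items() if n < 0}
        if bad:
            raise ValueError(f"negative codon counts: {bad}")

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def family_counts(self, aa: str, code: GeneticCode) -> dict[str, int]:
        return {c: self.get(c) for c in code.family_of[aa]}

    @classmethod
    def from_cds(cls, cds: CodingSequence) -> "CodonCountTable":
        return cls(counts=dict(Counter(cds.sense_codons)), source_id=cds.identifier)

    @classmethod
    def from_tsv(cls, path: str | Path, source_id: str = "") -> "CodonCountTable":
        """Read a two-column TSV (codon, count); '#' lines are comments."""
        path = Path(path)
        counts: dict[str, int] = {}
        with open(path) as handle:
            for row in csv.reader(handle, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0].lower() == "codon":
                    continue
                codon = row[0].strip().upper().replace("U", "T")
                counts[codon] = counts.get(codon, 0) + int(row[1])
        return cls(counts=counts, source_id=source_id or path.stem)


def count_codons(cds: CodingSequence) -> CodonCountTable:
    """Count sense codons of a CDS; the terminal stop is excluded."""
    return CodonCountTable.from_cds(cds)


@dataclass(frozen=True)
class CompositionSummary:
    """Nucleotide composition of a full ORF (stop codon included)."""

    n_A: int
    n_T: int
    n_G: int
    n_C: int

    @property
    def length(self) -> int:
        return self.n_A + self.n_T + self.n_G + self.n_C

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.length

    @property
    def pct_A(self) -> float:
        return self._pct(self.n_A)

    @property
    def pct_T(self) -> float:
        return self._pct(self.n_T)

    @property
    def pct_G(self) -> float:
        return self._pct(self.n_G)

    @property
    def pct_C(self) -> float:
        return self._pct(self.n_C)

    @property
    def pct_AT(self) -> float:
        return self._pct(self.n_A + self.n_T)

    @property
    def pct_GC(self) -> float:
        return self._pct(self.n_G + self.n_C)

    @classmethod
    def from_counts(cls, n_A: int, n_T: int, n_G: int, n_C: int) -> "CompositionSummary":
        return cls(n_A=n_A, n_T=n_T, n_G=n_G, n_C=n_C)


def composition(cds: CodingSequence) -> CompositionSummary:
    """Nucleotide composition over the full ORF, stop codon included."""
    c = Counter(cds.sequence)
    return CompositionSummary(n_A=c["A"], n_T=c["T"], n_G=c["G"], n_C=c["C"])


def gc3_synonymous(counts: CodonCountTable, code: GeneticCode | None = None) -> float:
    """Synonymous GC3 in percent.

    Fraction of G|C-ending codons among codons of multi-codon amino acids;
    Met, Trp and stop codons are excluded from numerator and denominator.
    """
    code = code or standard_code()
    num = den = 0
    for aa, family in code.multi_codon_families().items():
        for codon in family:
            n = counts.get(codon)
            den += n
            if codon[2] in GC_BASES:
                num += n
    if den == 0:
        raise UndefinedResultError("no synonymous codons present; GC3 undefined")
    return 100.0 * num / den


@dataclass(frozen=True)
class RSCUTable:
    """Per-codon RSCU values; ``None`` marks codons of absent amino acids."""

    values: dict[str, float | None]
    family_totals: dict[str, int]
    source_id: str = ""

    def get(self, codon: str) -> float | None:
        return self.values.get(codon)


def rscu(counts: CodonCountTable, code: GeneticCode | None = None) -> RSCUTable:
    """RSCU for every codon of the 18 multi-codon amino acids.

    ``RSCU = count * n_i / family_total``; six-fold families are normalised
    jointly over all six codons.  Amino acids with zero occurrences get
    ``None`` (undefined, not zero).  Met and Trp are excluded.
    """
    code = code or standard_code()
    values: dict[str, float | None] = {}
    totals: dict[str, int] = {}
    for aa, family in code.multi_codon_families().items():
        total = sum(counts.get(c) for c in family)
        totals[aa] = total
        for codon in family:
            values[codon] = None if total == 0 else counts.get(codon) * len(family) / total
    return RSCUTable(values=values, family_totals=totals, source_id=counts.source_id)


@dataclass(frozen=True)
class ENCResult:
    """Observed Wright Nc together with the GC3-based expectation."""

    nc_observed: float
    f_bar: dict[int, float] = field(repr=False)
    gc3_pct: float = float("nan")
    enc_expected: float = float("nan")

    @property
    def f_bar_2(self) -> float:
        return self.f_bar[2]

    @property
    def f_bar_3(self) -> float:
        return self.f_bar[3]

    @property
    def f_bar_4(self) -> float:
        return self.f_bar[4]

    @property
    def f_bar_6(self) -> float:
        return self.f_bar[6]


def _family_homozygosity(family_counts: dict[str, int]) -> float | None:
    """Wright's bias-corrected homozygosity F = (n Σp² − 1)/(n − 1).

    Returns None for unusable families (n < 2, or F ≤ 0 which can occur
    for small n with near-uniform usage).
    """
    n = sum(family_counts.values())
    if n < 2:
        return None
    sum_p2 = sum((k / n) ** 2 for k in family_counts.values())
    f = (n * sum_p2 - 1.0) / (n - 1.0)
    return f if f > 0 else None


def enc_observed(counts: CodonCountTable, code: GeneticCode | None = None) -> ENCResult:
    """Wright's observed effective number of codons.

    Per-family homozygosities are averaged within each degeneracy class
    (2-, 3-, 4-, six-fold); families with n < 2 or F ≤ 0 are dropped from
    their class mean.  An empty three-fold class (Ile absent) is imputed as
    the mean of the two- and four-fold class means; an empty class of any
    other degeneracy is an error.  Nc is capped at 61.

    The result also carries synonymous GC3 and the composition-only ENC
    expectation evaluated at that GC3.
    """
    code = code or standard_code()
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.multi_codon_families().items():
        f = _family_homozygosity(counts.family_counts(aa, code))
        if f is not None:
            by_class[len(family)].append(f)

    f_bar: dict[int, float] = {}
    for k, fs in by_class.items():
        if fs:
            f_bar[k] = sum(fs) / len(fs)
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    missing = [k for k in (2, 3, 4, 6) if k not in f_bar]
    if missing:
        raise UndefinedResultError(
            f"no usable families of degeneracy {missing}; Nc undefined"
        )

    nc = 2.0 + 9.0 / f_bar[2] + 1.0 / f_bar[3] + 5.0 / f_bar[4] + 3.0 / f_bar[6]
    nc = min(nc, NC_MAX)

    try:
        gc3 = gc3_synonymous(counts, code)
        expected = enc_expected(gc3 / 100.0)
    except UndefinedResultError:  # pragma: no cover - unreachable if Nc defined
        gc3 = expected = float("nan")
    return ENCResult(nc_observed=nc, f_bar=f_bar, gc3_pct=gc3, enc_expected=expected)


def enc_expected(gc3_fraction: float) -> float:
    """ENC expected from third-base composition alone.

    ``ENC(s) = 2 + s + 29 / (s² + (1−s)²)`` with ``s`` the GC3 fraction
    in [0, 1].  Exact evaluation, no capping.
    """
    s = gc3_fraction
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3 fraction must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)
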