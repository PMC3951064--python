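"""Rare-codon analysis against a host codon-usage reference.

Each codon's genomic usage is rescaled so the most-used codon of every
synonymous family scores 100; a codon scoring below a threshold (default
30) is a *rare* codon, likely decoded by a scarce tRNA and a potential
drag on translation.  The per-gene summary is the percentage of codons in
the CDS that are rare.

The bundled human reference is the codon-usage-database (Kazusa) tally of
GenBank human CDSs, in occurrences per thousand codons; any consistent
unit works since only within-family ratios matter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .codon_metrics import CodonCountTable
from .genetic_code import GeneticCode, standard_code
from .seqio import CodingSequence

__all__ = [
    "ReferenceUsageTable",
    "RareCodonReport",
    "build_relative_scores",
    "rare_fraction",
    "human_reference",
]

DEFAULT_THRESHOLD = 30.0


@dataclass(frozen=True)
class ReferenceUsageTable:
    """Species codon-usage frequencies with family-relative scores.

    ``usage`` must cover all 61 sense codons.  ``relative_score`` is empty
    until :func:`build_relative_scores` fills it (score 100 = the family's
    most-used codon; single-codon families score 100 by definition).
    """

    species: str
    usage: dict[str, float]
    relative_score: dict[str, float] | None = None

    @classmethod
    def from_tsv(cls, path: str | Path, species: str = "") -> "ReferenceUsageTable":
        usage: dict[str, float] = {}
        with open(path) as handle:
            for row in csv.reader(handle, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0].lower() == "codon":
                    continue
                usage[row[0].strip().upper().replace("U", "T")] = float(row[1])
        return cls(species=species or Path(path).stem, usage=usage)


def build_relative_scores(
    usage: ReferenceUsageTable, code: GeneticCode | None = None
) -> ReferenceUsageTable:
    """Rescale usage within each synonymous family to a 0–100 score."""
    code = code or standard_code()
    missing = sorted(set(code.sense_codons) - set(usage.usage))
    if missing:
        raise ValueError(f"reference table missing sense codons: {missing}")
    scores: dict[str, float] = {}
    for family in code.family_of.values():
        top = max(usage.usage[c] for c in family)
        for codon in family:
            scores[codon] = 100.0 if len(family) == 1 else 100.0 * usage.usage[codon] / top
    return ReferenceUsageTable(
        species=usage.species, usage=dict(usage.usage), relative_score=scores
    )


def human_reference(code: GeneticCode | None = None) -> ReferenceUsageTable:
    """The bundled human codon-usage reference, scored and ready to use."""
    with resources.as_file(
        resources.files("codonuse.data") / "human_codon_usage.tsv"
    ) as path:
        table = ReferenceUsageTable.from_tsv(path, species="Homo sapiens")
    return build_relative_scores(table, code)


@dataclass(frozen=True)
class RareCodonReport:
    """Per-position relative scores and the low-frequency-codon percentage."""

    per_codon_scores: tuple[float, ...]
    pct_low: float
    threshold: float
    source_id: str = ""

    @property
    def pct_low_rounded(self) -> int:
        """Whole-percent figure for report parity with published tables."""
        return round(self.pct_low)


def _scores_of(ref: ReferenceUsageTable) -> dict[str, float]:
    if ref.relative_score is None:
        raise ValueError("reference table has no relative scores; "
                         "run build_relative_scores first")
    return ref.relative_score


def rare_fraction(
    cds: CodingSequence | CodonCountTable,
    ref: ReferenceUsageTable,
    threshold: float = DEFAULT_THRESHOLD,
) -> RareCodonReport:
    """Percentage of sense codons scoring below ``threshold``.

    Accepts either a CDS (per-position score track preserved, mirroring a
    codon-frequency-distribution plot) or a bare codon-count table (track
    expanded in codon-sorted order).
    """
    scores = _scores_of(ref)
    if isinstance(cds, CodonCountTable):
        track = tuple(
            scores[c] for c in sorted(cds.counts) for _ in range(cds.counts[c])
        )
        source = cds.source_id
    else:
        track = tuple(scores[c] for c in cds.sense_codons)
        source = cds.identifier
    n_low = sum(1 for s in track if s < threshold)
    pct = 100.0 * n_low / len(track) if track else 0.0
    return RareCodonReport(
        per_codon_scores=track, pct_low=pct, threshold=threshold, source_id=source
    )
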