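"""Synthetic coding sequences with controlled codon-usage structure.

Generates CDSs whose interior codons are drawn i.i.d. — amino acid from
``aa_probs``, then codon from that amino acid's ``family_probs`` — so
that every codon-usage estimator can be exercised against known truth:
with family probabilities ``p`` the expected RSCU of a codon is
``n_i * p`` and extreme probability vectors drive Wright's Nc to its 20
(one codon per family) and 61 (uniform usage) limits.  No dinucleotide
or positional structure is simulated; the statistics under test are
composition-free of it.

Also exposes the packaged per-gene codon-count fixtures of the four
albumin-superfamily CDSs (ALB, AFP, AFM, VDBP) so that every printed
index can be recomputed without sequence downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .codon_metrics import CodonCountTable
from .genetic_code import GeneticCode, standard_code
from .seqio import CodingSequence

__all__ = [
    "UsageSpec",
    "generate_cds",
    "uniform_usage_spec",
    "single_codon_usage_spec",
    "table3_fixture",
    "nucleotide_count_fixture",
    "FIXTURE_GENES",
]

FIXTURE_GENES = ("ALB", "AFP", "AFM", "VDBP")

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class UsageSpec:
    """Sampling model for a synthetic CDS.

    ``aa_probs`` weights the 20 amino acids for interior positions;
    ``family_probs`` gives, per amino acid, the probability of each of its
    synonymous codons (codon order as in ``GeneticCode.family_of``).
    Amino acids absent from ``family_probs`` default to uniform usage.
    """

    aa_probs: dict[str, float]
    family_probs: dict[str, tuple[float, ...]] = field(default_factory=dict)
    n_codons: int = 1000
    seed: int = 0

    def validate(self, code: GeneticCode) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        total = sum(self.aa_probs.values())
        if not self.aa_probs or abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"aa_probs must sum to 1 (got {total})")
        if all(p == 0 for p in self.aa_probs.values()):
            raise ValueError("degenerate spec: all amino-acid probabilities zero")
        for aa, probs in self.family_probs.items():
            family = code.family_of[aa]
            if len(probs) != len(family):
                raise ValueError(
                    f"{aa}: {len(probs)} probabilities for {len(family)} codons"
                )
            if abs(sum(probs) - 1.0) > _PROB_TOL:
                raise ValueError(f"{aa}: family probabilities must sum to 1")


def generate_cds(spec: UsageSpec, code: GeneticCode | None = None) -> CodingSequence:
    """Draw a CDS: ATG + ``n_codons`` i.i.d. interior codons + TAA.

    Reproducible: the same seed yields the identical sequence.  The seed
    is recorded in the identifier (and hence in FASTA headers).
    """
    code = code or standard_code()
    spec.validate(code)
    rng = np.random.default_rng(spec.seed)

    aas = sorted(spec.aa_probs)
    aa_p = np.array([spec.aa_probs[a] for a in aas])
    aa_p = aa_p / aa_p.sum()
    aa_draws = rng.choice(len(aas), size=spec.n_codons, p=aa_p)

    # draw codons vectorised per amino acid (deterministic order over aas)
    interior = np.empty(spec.n_codons, dtype=object)
    for idx, aa in enumerate(aas):
        mask = aa_draws == idx
        m = int(mask.sum())
        if m == 0:
            continue
        family = code.family_of[aa]
        probs = spec.family_probs.get(aa)
        if probs is None:
            picks = rng.integers(len(family), size=m)
        else:
            picks = rng.choice(len(family), size=m, p=np.asarray(probs) / sum(probs))
        interior[mask] = [family[j] for j in picks]

    codons = ("ATG", *interior.tolist(), "TAA")
    return CodingSequence(identifier=f"synthetic_seed{spec.seed}", codons=codons)


def uniform_usage_spec(n_codons: int = 1000, seed: int = 0,
                       code: GeneticCode | None = None) -> UsageSpec:
    """Uniform amino acids, uniform synonymous usage: the Nc → 61 regime."""
    code = code or standard_code()
    aas = sorted(code.family_of)
    return UsageSpec(aa_probs={a: 1.0 / len(aas) for a in aas}, n_codons=n_codons,
                     seed=seed)


def single_codon_usage_spec(n_codons: int = 1000, seed: int = 0,
                            code: GeneticCode | None = None) -> UsageSpec:
    """One codon per family (the first, deterministically): the Nc = 20 regime."""
    code = code or standard_code()
    aas = sorted(code.family_of)
    family_probs = {
        aa: tuple(1.0 if i == 0 else 0.0 for i in range(len(code.family_of[aa])))
        for aa in aas
    }
    return UsageSpec(aa_probs={a: 1.0 / len(aas) for a in aas},
                     family_probs=family_probs, n_codons=n_codons, seed=seed)


def _read_data(name: str) -> CodonCountTable:
    with resources.as_file(resources.files("codonuse.data") / name) as path:
        return CodonCountTable.from_tsv(path)


def table3_fixture(gene: str) -> CodonCountTable:
    """Packaged per-codon counts of one albumin-superfamily CDS.

    Covers the 59 sense codons of the 18 multi-codon amino acids
    (ATG and TGG are not part of the published per-codon tally).
    """
    gene = gene.upper()
    if gene not in FIXTURE_GENES:
        raise ValueError(f"unknown gene {gene!r}; expected one of {FIXTURE_GENES}")
    table = _read_data(f"counts_{gene.lower()}.tsv")
    return CodonCountTable(counts=table.counts, source_id=gene)


def nucleotide_count_fixture(gene: str) -> tuple[int, int, int, int]:
    """Packaged full-ORF nucleotide counts (A, T, G, C) for one gene."""
    gene = gene.upper()
    with resources.as_file(
        resources.files("codonuse.data") / "nucleotide_counts.tsv"
    ) as path:
        with open(path) as handle:
            for line in handle:
                if line.startswith("#") or line.startswith("gene"):
                    continue
                fields = line.split()
                if fields and fields[0] == gene:
                    return tuple(int(x) for x in fields[1:5])  # type: ignore[return-value]
    raise ValueError(f"unknown gene {gene!r}; expected one of {FIXTURE_GENES}")
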