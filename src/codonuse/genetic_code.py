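"""Standard genetic code with synonymous-family structure.

Codon-usage statistics need more than a codon→amino-acid map: RSCU and
Wright's effective number of codons operate on *synonymous families* (the
set of codons encoding one amino acid) grouped by degeneracy (1, 2, 3, 4
or 6 codons per family).  This module wraps NCBI translation table 1 in
that family-oriented view.

Codons are DNA-alphabet, upper case (``ATG`` not ``AUG``) throughout the
package; RNA input is normalised at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

STOP_SYMBOL = "*"

#: nucleotides considered G|C for composition / GC3 purposes
GC_BASES = frozenset("GC")


@dataclass(frozen=True)
class GeneticCode:
    """The standard nuclear genetic code, indexed by synonymous family.

    Attributes
    ----------
    codon_to_aa:
        64-entry map, DNA codon → one-letter amino acid or ``"*"`` for stop.
    family_of:
        amino acid → tuple of its synonymous codons (sorted); stop excluded.
    degeneracy:
        amino acid → number of synonymous codons (1, 2, 3, 4 or 6).
        Leu, Ser and Arg are six-fold families: the two-codon and four-codon
        blocks of each are a single family, not separate ones.
    """

    codon_to_aa: dict[str, str]
    family_of: dict[str, tuple[str, ...]] = field(init=False)
    degeneracy: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        families: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            if aa != STOP_SYMBOL:
                families.setdefault(aa, []).append(codon)
        object.__setattr__(
            self, "family_of", {aa: tuple(sorted(c)) for aa, c in families.items()}
        )
        object.__setattr__(
            self, "degeneracy", {aa: len(c) for aa, c in self.family_of.items()}
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP_SYMBOL))

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa == STOP_SYMBOL))

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP_SYMBOL

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def multi_codon_families(self) -> dict[str, tuple[str, ...]]:
        """Families with ≥2 synonymous codons (the 18 RSCU-relevant ones)."""
        return {aa: fam for aa, fam in self.family_of.items() if len(fam) > 1}


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard nuclear code (NCBI table 1): 61 sense codons, 3 stops."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP_SYMBOL
    return GeneticCode(codon_to_aa=mapping)
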