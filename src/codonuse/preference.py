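"""Preferred-codon identification and the A+U vs G+C third-base tally.

For each amino-acid family the *preferred* codon is the RSCU argmax
(ties possible).  Tallying how many families prefer an A/U-ending versus
a G/C-ending codon summarises whether third-base preference tracks the
genome's composition: AT-rich genes preferring A/U-ending codons is the
signature of composition rather than translational selection.

Two row schemes are supported.  ``amino_acid_families`` tallies the 18
multi-codon amino acids, Leu/Ser/Arg each a single six-codon row.
``display_rows`` mirrors conventional RSCU tables, which print Ser as two
blocks (UCU–UCG and AGU/AGC) and Arg as two (CGU–CGG and AGA/AGG): 20
rows, with argmax taken within each block over the jointly-normalised
RSCU values.  Rows whose preferred set is not a single codon are counted
as ties and excluded from both tallies by default; pass
``ties="same_ending"`` to keep tie rows whose codons all share an A/U or
G/C ending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .codon_metrics import RSCUTable
from .genetic_code import GC_BASES, GeneticCode, standard_code

__all__ = ["PreferenceSummary", "preferred_codons", "au_gc_tally"]

RowScheme = Literal["amino_acid_families", "display_rows"]
TiePolicy = Literal["exclude", "same_ending"]

# conventional RSCU-table display order with Ser and Arg split in two blocks
_DISPLAY_SPLITS = {
    "S": (("TCT", "TCC", "TCA", "TCG"), ("AGT", "AGC")),
    "R": (("CGT", "CGC", "CGA", "CGG"), ("AGA", "AGG")),
}


@dataclass(frozen=True)
class PreferenceSummary:
    """Preferred codons per row plus the A+U / G+C tally."""

    preferred: dict[str, frozenset[str]]
    au_count: int
    gc_count: int
    tie_rows: int
    undefined_rows: int
    row_scheme: RowScheme
    source_id: str = ""


def _rows(scheme: RowScheme, code: GeneticCode) -> dict[str, tuple[str, ...]]:
    rows: dict[str, tuple[str, ...]] = {}
    for aa, family in sorted(code.multi_codon_families().items()):
        if scheme == "display_rows" and aa in _DISPLAY_SPLITS:
            for i, block in enumerate(_DISPLAY_SPLITS[aa], start=1):
                rows[f"{aa}{i}"] = block
        else:
            rows[aa] = family
    return rows


def preferred_codons(
    table: RSCUTable,
    scheme: RowScheme = "amino_acid_families",
    code: GeneticCode | None = None,
) -> dict[str, frozenset[str]]:
    """Per row, the codon(s) with maximal RSCU; absent amino acids omitted."""
    code = code or standard_code()
    out: dict[str, frozenset[str]] = {}
    for row, codons in _rows(scheme, code).items():
        values = {c: table.get(c) for c in codons}
        if any(v is None for v in values.values()):
            continue
        top = max(values.values())
        out[row] = frozenset(c for c, v in values.items() if v == top)
    return out


def au_gc_tally(
    table: RSCUTable,
    scheme: RowScheme = "amino_acid_families",
    ties: TiePolicy = "exclude",
    code: GeneticCode | None = None,
) -> PreferenceSummary:
    """Count rows preferring A/U-ending vs G/C-ending codons.

    The tally is deterministic given the RSCU table, scheme and tie
    policy.  ``au_count + gc_count + tie_rows + undefined_rows`` equals
    the number of rows under the chosen scheme.
    """
    code = code or standard_code()
    all_rows = _rows(scheme, code)
    preferred = preferred_codons(table, scheme, code)
    au = gc = tie = 0
    for row, top in preferred.items():
        endings = {("GC" if c[2] in GC_BASES else "AU") for c in top}
        is_tie = len(top) > 1
        if is_tie and (ties == "exclude" or len(endings) > 1):
            tie += 1
        elif endings == {"AU"}:
            au += 1
        else:
            gc += 1
    return PreferenceSummary(
        preferred=preferred,
        au_count=au,
        gc_count=gc,
        tie_rows=tie,
        undefined_rows=len(all_rows) - len(preferred),
        row_scheme=scheme,
        source_id=table.source_id,
    )
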