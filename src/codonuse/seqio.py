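"""Sequence input, ORF selection and translation.

Reads nucleotide FASTA (DNA or mRNA alphabet; U is normalised to T),
extracts the open reading frame, and translates it under the standard
genetic code.  The ORF rule is: the longest forward-strand reading frame
that starts at ATG, ends at a stop codon and contains no internal stop;
ties are broken in favour of the 5'-most start.  The annotated CDSs of
the albumin-superfamily mRNAs all satisfy this rule.

Ambiguity codes (N, R, Y, ...) are rejected with an explicit error rather
than skipped: every downstream statistic assumes fully resolved codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .genetic_code import GeneticCode, standard_code

__all__ = [
    "NucleotideSequence",
    "CodingSequence",
    "GeneticCode",
    "standard_code",
    "read_fasta",
    "extract_orf",
    "translate",
    "FastaParseError",
    "SequenceValidationError",
    "OrfNotFoundError",
]

_VALID_BASES = frozenset("ACGT")


class FastaParseError(ValueError):
    """Raised when a file is not parseable as FASTA."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,U}."""


class OrfNotFoundError(ValueError):
    """Raised when no ATG...stop reading frame exists on the forward strand."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated nucleotide sequence (DNA alphabet, upper case)."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        normalized = self.residues.upper().replace("U", "T")
        bad = sorted(set(normalized) - _VALID_BASES)
        if bad:
            raise SequenceValidationError(
                f"{self.identifier}: invalid characters {bad}; "
                "only A/C/G/T (or U) are accepted"
            )
        if not normalized:
            raise SequenceValidationError(f"{self.identifier}: empty sequence")
        object.__setattr__(self, "residues", normalized)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingSequence:
    """A validated ORF: ATG-initiated, exactly one terminal stop codon.

    ``codons`` includes the terminal stop; sense codons are everything
    before it.  All codon-usage statistics except full-ORF nucleotide
    composition operate on the sense codons only.
    """

    identifier: str
    codons: tuple[str, ...]

    def __post_init__(self) -> None:
        code = standard_code()
        if len(self.codons) < 2:
            raise SequenceValidationError(
                f"{self.identifier}: an ORF needs at least a start and a stop codon"
            )
        for c in self.codons:
            if len(c) != 3 or set(c) - _VALID_BASES:
                raise SequenceValidationError(f"{self.identifier}: invalid codon {c!r}")
        if self.codons[0] != "ATG":
            raise SequenceValidationError(f"{self.identifier}: ORF must start with ATG")
        if not code.is_stop(self.codons[-1]):
            raise SequenceValidationError(
                f"{self.identifier}: ORF must end with a stop codon"
            )
        internal = [c for c in self.codons[:-1] if code.is_stop(c)]
        if internal:
            raise SequenceValidationError(
                f"{self.identifier}: internal stop codon(s) {internal}"
            )

    @property
    def length_bp(self) -> int:
        return 3 * len(self.codons)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return self.codons[:-1]

    @property
    def sequence(self) -> str:
        return "".join(self.codons)

    @classmethod
    def from_sequence(cls, identifier: str, sequence: str) -> "CodingSequence":
        seq = sequence.upper().replace("U", "T")
        if len(seq) % 3:
            raise SequenceValidationError(
                f"{identifier}: CDS length {len(seq)} not divisible by 3"
            )
        return cls(identifier, tuple(seq[i : i + 3] for i in range(0, len(seq), 3)))


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (possibly multi-record, wrapped) FASTA file.

    Records keep file order; U→T normalisation and case folding are applied.
    Raises :class:`FastaParseError` for an empty file or content before the
    first header (naming the offending line), and
    :class:`SequenceValidationError` for non-ACGTU characters.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno} precedes the first '>' header; "
                    "not a FASTA file"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty input, no FASTA records")
    records = [
        NucleotideSequence(identifier=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}: empty input, no FASTA records")
    return records


def _orf_candidates(residues: str, code: GeneticCode) -> Iterable[tuple[int, int]]:
    """Yield (start, end) of every ATG-initiated frame closed by its first
    in-frame stop, end exclusive of nothing (stop included)."""
    n = len(residues)
    start = residues.find("ATG")
    while start != -1:
        for pos in range(start, n - 2, 3):
            codon = residues[pos : pos + 3]
            if code.is_stop(codon):
                yield start, pos + 3
                break
        start = residues.find("ATG", start + 1)


def extract_orf(seq: NucleotideSequence, code: GeneticCode | None = None) -> CodingSequence:
    """Select the longest forward-strand ATG...stop ORF (5'-most on ties)."""
    code = code or standard_code()
    if len(seq) < 6:
        raise OrfNotFoundError(
            f"{seq.identifier}: sequence of {len(seq)} bp too short for an ORF"
        )
    best: tuple[int, int] | None = None
    for start, end in _orf_candidates(seq.residues, code):
        if best is None or (end - start) > (best[1] - best[0]):
            best = (start, end)
        # equal length at a later start never replaces the 5'-most hit
    if best is None:
        raise OrfNotFoundError(f"{seq.identifier}: no ATG...stop reading frame found")
    start, end = best
    return CodingSequence.from_sequence(seq.identifier, seq.residues[start:end])


def translate(cds: CodingSequence, code: GeneticCode | None = None) -> str:
    """Translate a CDS; the terminal stop is omitted from the protein."""
    code = code or standard_code()
    return "".join(code.translate_codon(c) for c in cds.sense_codons)
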