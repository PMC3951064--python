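"""GRAVY: grand average of hydropathy of a protein.

GRAVY is the arithmetic mean of per-residue hydropathy indices,
``(1/N) Σ K_i``, under the Kyte–Doolittle scale (Ile +4.5 ... Arg −4.5).
Negative scores indicate a hydrophilic, water-soluble protein — the
expected regime for serum transport proteins.  The scale is injectable;
Kyte–Doolittle is the default because it is the ProtParam convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

__all__ = ["HydropathyScale", "GravyResult", "gravy", "KYTE_DOOLITTLE"]


@dataclass(frozen=True)
class HydropathyScale:
    """Amino acid → hydropathy index; must cover all 20 standard residues."""

    index: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = sorted(set("ACDEFGHIKLMNPQRSTVWY") - set(self.index))
        if missing:
            raise ValueError(f"hydropathy scale {self.name!r} missing residues {missing}")


KYTE_DOOLITTLE = HydropathyScale(index=dict(_KYTE_DOOLITTLE), name="Kyte-Doolittle")


@dataclass(frozen=True)
class GravyResult:
    score: float
    n_residues: int


def gravy(protein: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> GravyResult:
    """Mean hydropathy of a protein string.

    Raises ``ValueError`` on an empty string or residues outside the scale
    (stop symbols never reach this function; translation drops them).
    """
    if not protein:
        raise ValueError("GRAVY is undefined for an empty protein")
    unknown = sorted(set(protein) - set(scale.index))
    if unknown:
        raise ValueError(f"unknown residue symbol(s) {unknown} for scale {scale.name!r}")
    total = sum(scale.index[aa] for aa in protein)
    return GravyResult(score=total / len(protein), n_residues=len(protein))
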