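"""Shared fixtures: the genetic code, packaged count tables, printed values."""

import csv
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pytest

from codonuse import FIXTURE_GENES, standard_code, table3_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def gene_counts():
    """Packaged per-gene codon-count tables for the four superfamily CDSs."""
    return {gene: table3_fixture(gene) for gene in FIXTURE_GENES}


@pytest.fixture(scope="session")
def printed_rscu():
    """Published 2-dp RSCU values per codon per gene."""
    table: dict[str, dict[str, Decimal]] = {g: {} for g in FIXTURE_GENES}
    with open(DATA_DIR / "table3_printed_rscu.tsv") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "codon":
                continue
            for gene, value in zip(FIXTURE_GENES, row[1:]):
                table[gene][row[0]] = Decimal(value)
    return table


def round2(x: float) -> Decimal:
    """Round half-up to 2 decimals, the convention of the printed tables."""
    return Decimal(str(x)).quantize(Decimal("0.01"), ROUND_HALF_UP)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(content: str, name: str = "input.fasta") -> Path:
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write
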