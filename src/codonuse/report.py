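"""Per-gene report assembly and TSV/JSON writers.

``analyze`` ties the pipeline together: for each input CDS (from FASTA)
or packaged count fixture it computes nucleotide composition, GRAVY,
GC3, observed and expected ENC, RSCU, the rare-codon percentage and the
A+U/G+C preference tally, exactly once each, into a ``GeneReport``.

Count-only inputs (the packaged fixtures) lack the sequence itself, so
composition and GRAVY are marked unavailable rather than guessed.

TSV output uses fixed float formatting (GC/AT 3 dp, ENC/GC3 2 dp, RSCU
2 dp, GRAVY 3 dp) and fixed ordering so reruns are byte-identical; JSON
carries full precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import codon_metrics, preference, protein_metrics, rare_codon, seqio
from .codon_metrics import (
    CodonCountTable,
    CompositionSummary,
    ENCResult,
    RSCUTable,
    enc_observed,
    rscu,
)
from .genetic_code import GeneticCode, standard_code
from .preference import PreferenceSummary, au_gc_tally
from .protein_metrics import GravyResult, gravy
from .rare_codon import RareCodonReport, ReferenceUsageTable, rare_fraction
from .seqio import CodingSequence
from .synthetic import FIXTURE_GENES, table3_fixture

__all__ = ["GeneReport", "analyze", "write_report", "AnalysisError"]

logger = logging.getLogger("codonuse")


class AnalysisError(RuntimeError):
    """All inputs failed to analyze."""


@dataclass(frozen=True)
class GeneReport:
    """All codon-usage statistics of one gene, from one CodingSequence."""

    identifier: str
    counts: CodonCountTable
    enc: ENCResult
    rscu: RSCUTable
    rare: RareCodonReport
    preference: PreferenceSummary
    orf_length_bp: int | None = None
    composition: CompositionSummary | None = None
    gravy: GravyResult | None = None


def _report_from_counts(
    identifier: str,
    counts: CodonCountTable,
    ref: ReferenceUsageTable,
    threshold: float,
    scheme: preference.RowScheme,
    code: GeneticCode,
    cds: CodingSequence | None = None,
) -> GeneReport:
    enc = enc_observed(counts, code)
    table = rscu(counts, code)
    rare = rare_fraction(cds if cds is not None else counts, ref, threshold)
    pref = au_gc_tally(table, scheme=scheme, code=code)
    comp = grav = length = None
    if cds is not None:
        comp = codon_metrics.composition(cds)
        grav = gravy(seqio.translate(cds, code))
        length = cds.length_bp
    return GeneReport(
        identifier=identifier,
        counts=counts,
        enc=enc,
        rscu=table,
        rare=rare,
        preference=pref,
        orf_length_bp=length,
        composition=comp,
        gravy=grav,
    )


def analyze(
    fasta_paths: Sequence[str | Path] = (),
    fixture_genes: Sequence[str] = (),
    rare_threshold: float = rare_codon.DEFAULT_THRESHOLD,
    reference: ReferenceUsageTable | None = None,
    scheme: preference.RowScheme = "display_rows",
    code: GeneticCode | None = None,
) -> list[GeneReport]:
    """Analyze FASTA records and/or packaged count fixtures.

    Per-input failures are logged and skipped; if every input fails an
    :class:`AnalysisError` is raised.  Output order is deterministic:
    FASTA records in file order, then fixtures in the order given.
    """
    code = code or standard_code()
    ref = reference if reference is not None else rare_codon.human_reference(code)
    reports: list[GeneReport] = []
    failures: list[str] = []

    for path in fasta_paths:
        t0 = time.perf_counter()
        try:
            for record in seqio.read_fasta(path):
                cds = seqio.extract_orf(record, code)
                counts = codon_metrics.count_codons(cds)
                reports.append(
                    _report_from_counts(
                        record.identifier, counts, ref, rare_threshold, scheme,
                        code, cds=cds,
                    )
                )
        except Exception as exc:  # noqa: BLE001 - per-input failure policy
            failures.append(str(path))
            logger.error("failed on %s: %s", path, exc)
        else:
            logger.info("analyzed %s in %.1f ms", path,
                        1e3 * (time.perf_counter() - t0))

    for gene in fixture_genes:
        try:
            counts = table3_fixture(gene)
            reports.append(
                _report_from_counts(gene.upper(), counts, ref, rare_threshold,
                                    scheme, code)
            )
        except Exception as exc:  # noqa: BLE001
            failures.append(gene)
            logger.error("failed on fixture %s: %s", gene, exc)

    if failures and not reports:
        raise AnalysisError(f"all inputs failed: {failures}")
    return reports


# ---------------------------------------------------------------- writers

def _fmt(value: float | None, digits: int) -> str:
    return "NA" if value is None else f"{value:.{digits}f}"


_SUMMARY_COLUMNS = (
    "gene", "orf_length_bp", "total_codons", "gravy", "pct_AT", "pct_GC",
    "gc3_pct", "enc_observed", "enc_expected", "rare_pct", "rare_threshold",
    "preference_scheme", "au_count", "gc_count", "tie_rows",
)


def _summary_row(r: GeneReport) -> list[str]:
    comp = r.composition
    return [
        r.identifier,
        "NA" if r.orf_length_bp is None else str(r.orf_length_bp),
        str(r.counts.total_codons),
        _fmt(r.gravy.score if r.gravy else None, 3),
        _fmt(comp.pct_AT if comp else None, 3),
        _fmt(comp.pct_GC if comp else None, 3),
        _fmt(r.enc.gc3_pct, 2),
        _fmt(r.enc.nc_observed, 2),
        _fmt(r.enc.enc_expected, 2),
        str(r.rare.pct_low_rounded),
        _fmt(r.rare.threshold, 0),
        r.preference.row_scheme,
        str(r.preference.au_count),
        str(r.preference.gc_count),
        str(r.preference.tie_rows),
    ]


def _rscu_rows(r: GeneReport, code: GeneticCode) -> Iterable[list[str]]:
    for aa, family in sorted(code.multi_codon_families().items()):
        for codon in family:
            value = r.rscu.get(codon)
            yield [
                r.identifier, aa, codon, str(r.counts.get(codon)),
                _fmt(value, 2),
                "yes" if any(codon in s for s in r.preference.preferred.values())
                and value is not None else "no",
            ]


def _json_payload(r: GeneReport) -> dict:
    payload: dict = {
        "identifier": r.identifier,
        "orf_length_bp": r.orf_length_bp,
        "counts": dict(sorted(r.counts.counts.items())),
        "total_codons": r.counts.total_codons,
        "enc": {
            "nc_observed": r.enc.nc_observed,
            "f_bar": {str(k): v for k, v in sorted(r.enc.f_bar.items())},
            "gc3_pct": r.enc.gc3_pct,
            "enc_expected": r.enc.enc_expected,
        },
        "rscu": dict(sorted(r.rscu.values.items())),
        "rscu_family_totals": dict(sorted(r.rscu.family_totals.items())),
        "rare": {
            "pct_low": r.rare.pct_low,
            "pct_low_rounded": r.rare.pct_low_rounded,
            "threshold": r.rare.threshold,
        },
        "preference": {
            "scheme": r.preference.row_scheme,
            "au_count": r.preference.au_count,
            "gc_count": r.preference.gc_count,
            "tie_rows": r.preference.tie_rows,
            "preferred": {k: sorted(v) for k, v in sorted(r.preference.preferred.items())},
        },
        "composition": None,
        "gravy": None,
    }
    if r.composition is not None:
        c = r.composition
        payload["composition"] = {
            "n_A": c.n_A, "n_T": c.n_T, "n_G": c.n_G, "n_C": c.n_C,
            "pct_A": c.pct_A, "pct_T": c.pct_T, "pct_G": c.pct_G, "pct_C": c.pct_C,
            "pct_AT": c.pct_AT, "pct_GC": c.pct_GC,
        }
    if r.gravy is not None:
        payload["gravy"] = dataclasses.asdict(r.gravy)
    return payload


def write_report(
    reports: Sequence[GeneReport],
    fmt: str = "tsv",
    out_dir: str | Path = ".",
    code: GeneticCode | None = None,
) -> list[Path]:
    """Write reports as TSV (summary + long RSCU table) or JSON.

    Returns the paths written.  Raises ``ValueError`` on an empty report
    list and propagates I/O errors for unwritable paths.
    """
    if not reports:
        raise ValueError("no reports to write")
    code = code or standard_code()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if fmt == "tsv":
        summary = out_dir / "summary.tsv"
        with open(summary, "w") as fh:
            fh.write("\t".join(_SUMMARY_COLUMNS) + "\n")
            for r in reports:
                fh.write("\t".join(_summary_row(r)) + "\n")
        written.append(summary)

        rscu_path = out_dir / "rscu.tsv"
        with open(rscu_path, "w") as fh:
            fh.write("gene\tamino_acid\tcodon\tcount\trscu\tpreferred\n")
            for r in reports:
                for row in _rscu_rows(r, code):
                    fh.write("\t".join(row) + "\n")
        written.append(rscu_path)
    elif fmt == "json":
        path = out_dir / "report.json"
        with open(path, "w") as fh:
            json.dump([_json_payload(r) for r in reports], fh, indent=2,
                      sort_keys=True)
            fh.write("\n")
        written.append(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'json'")
    return written


def configure_logging(quiet: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.ERROR if quiet else logging.INFO)
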