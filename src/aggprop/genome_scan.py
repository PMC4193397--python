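"""Proteome-wide application of the two classifiers.

Produces per-organism summaries (fAg, fC3, GC content, groEL copies, habitat)
in the schema of the study's per-genome table, plus per-protein calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

from .core_io import MIN_SCAN_LENGTH, ProteinRecord
from .model import Prediction
from .phylo_stats import mann_whitney

logger = logging.getLogger(__name__)


class Classifier(Protocol):
    """Anything that maps proteins to scored boolean predictions."""

    def predict_records(self, proteins: Sequence[ProteinRecord]) -> list[Prediction]: ...


@dataclass(frozen=True)
class ProteomeSummary:
    organism_id: str
    n_proteins: int
    n_excluded: int
    fAg: float
    fC3: float  # denominator: whole proteome
    fC3_within_agg: float  # denominator: predicted aggregation-prone subset
    gc: float | None = None
    groel_copies: int | None = None
    habitat: str | None = None

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0.0 <= self.fC3 <= self.fAg <= 1.0:
            raise ValueError("expected 0 <= fC3 <= fAg <= 1")


def scan(
    proteome: Sequence[ProteinRecord],
    agg_model: Classifier,
    c3_model: Classifier,
    organism_id: str = "",
    min_length: int = MIN_SCAN_LENGTH,
) -> tuple[ProteomeSummary, list[tuple[str, bool, float, bool | None, float | None]]]:
    """Classify a proteome with both models.

    fAg = predicted aggregation-prone / scanned proteins. The GroEL-obligate
    model is applied only to the predicted aggregation-prone subset;
    fC3 = obligate calls / scanned proteins (whole-proteome denominator; the
    within-subset fraction is also reported). Proteins shorter than
    ``min_length`` after sanitization are excluded and counted.

    Returns the summary and per-protein calls
    (id, agg_call, agg_conf, c3_call-or-None, c3_conf-or-None).
    """
    if not proteome:
        raise ValueError("empty proteome")
    scanned = [p for p in proteome if len(p.seq) >= min_length]
    excluded = len(proteome) - len(scanned)
    if excluded:
        logger.warning(
            "%s: excluded %d/%d proteins shorter than %d residues",
            organism_id or "<proteome>",
            excluded,
            len(proteome),
            min_length,
        )
    if not scanned:
        raise ValueError("no proteins pass the length policy")
    agg_preds = agg_model.predict_records(scanned)
    agg_by_id = {p.protein_id: p for p in agg_preds}
    agg_positive = [p for p, pred in zip(scanned, agg_preds) if pred.positive]
    c3_by_id: dict[str, Prediction] = {}
    if agg_positive:
        for pred in c3_model.predict_records(agg_positive):
            c3_by_id[pred.protein_id] = pred
    n = len(scanned)
    n_ag = len(agg_positive)
    n_c3 = sum(1 for pred in c3_by_id.values() if pred.positive)
    calls = []
    for p in scanned:
        ap = agg_by_id[p.id]
        cp = c3_by_id.get(p.id)
        calls.append(
            (
                p.id,
                ap.positive,
                ap.confidence,
                cp.positive if cp is not None else None,
                cp.confidence if cp is not None else None,
            )
        )
    summary = ProteomeSummary(
        organism_id=organism_id,
        n_proteins=n,
        n_excluded=excluded,
        fAg=n_ag / n,
        fC3=n_c3 / n,
        fC3_within_agg=(n_c3 / n_ag) if n_ag else 0.0,
    )
    return summary, calls


def annotate_summary(
    summary: ProteomeSummary,
    gc: Mapping[str, float] | None = None,
    groel_copies: Mapping[str, int] | None = None,
    habitat: Mapping[str, str] | None = None,
) -> ProteomeSummary:
    """Join user-supplied GC/copy-number/habitat columns onto a summary."""
    oid = summary.organism_id

    def lookup(table, name):
        if table is None:
            return None
        if oid not in table:
            logger.warning("organism %r missing from %s table", oid, name)
            return None
        return table[oid]

    return ProteomeSummary(
        organism_id=oid,
        n_proteins=summary.n_proteins,
        n_excluded=summary.n_excluded,
        fAg=summary.fAg,
        fC3=summary.fC3,
        fC3_within_agg=summary.fC3_within_agg,
        gc=lookup(gc, "GC"),
        groel_copies=lookup(groel_copies, "groEL-copies"),
        habitat=lookup(habitat, "habitat"),
    )


def stratify_by_copies(
    summaries: Sequence[ProteomeSummary],
) -> tuple[dict[int, list[float]], dict[tuple[int, int], float]]:
    """Group fC3 by groEL copy number with pairwise two-sided Mann-Whitney p's."""
    groups: dict[int, list[float]] = {}
    for s in summaries:
        if s.groel_copies is None:
            logger.warning("organism %r has no groEL copy number; skipped", s.organism_id)
            continue
        groups.setdefault(s.groel_copies, []).append(s.fC3)
    if len(groups) < 2:
        raise ValueError("need >= 2 groEL copy-number groups")
    keys = sorted(groups)
    pvalues: dict[tuple[int, int], float] = {}
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            _, p = mann_whitney(groups[ka], groups[kb], alternative="two-sided")
            pvalues[(ka, kb)] = p
    return groups, pvalues


SUMMARY_COLUMNS = [
    "organism_id",
    "n_proteins",
    "n_excluded",
    "fAg",
    "fC3",
    "fC3_within_agg",
    "gc",
    "groel_copies",
    "habitat",
]


def write_summaries(summaries: Sequence[ProteomeSummary], path) -> None:
    """Write summaries as a TSV in the documented column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            row = [
                s.organism_id,
                str(s.n_proteins),
                str(s.n_excluded),
                f"{s.fAg:.6f}",
                f"{s.fC3:.6f}",
                f"{s.fC3_within_agg:.6f}",
                "" if s.gc is None else f"{s.gc:.6f}",
                "" if s.groel_copies is None else str(s.groel_copies),
                s.habitat or "",
            ]
            fh.write("\t".join(row) + "\n")
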