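"""Training-set curation: solubility thresholds, multi-study label merging,
and redundancy reduction at a global-identity threshold.

The curated classes are ``soluble`` (high measured solubility, not a substrate
of any chaperone study), ``aggregation_prone`` (low measured solubility, or
chaperone-dependent in >= 2 distinct studies) and ``groel_obligate`` (Class 3
substrate membership, used by the second classifier).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .core_io import ProteinRecord

logger = logging.getLogger(__name__)

SOLUBLE = "soluble"
AGGREGATION_PRONE = "aggregation_prone"
GROEL_OBLIGATE = "groel_obligate"

SOLUBLE_THRESHOLD = 70.0  # strict: > 70 is soluble
AGGREGATION_THRESHOLD = 30.0  # strict: < 30 is aggregation-prone


@dataclass(frozen=True)
class LabelSource:
    """One labelling study: a solubility table or a substrate membership list."""

    name: str
    kind: str  # "continuous-solubility" | "membership"
    payload: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.kind not in ("continuous-solubility", "membership"):
            raise ValueError(f"unknown label source kind {self.kind!r}")

    @classmethod
    def membership(cls, name: str, ids: Iterable[str]) -> "LabelSource":
        ids = list(ids)
        if len(ids) != len(set(ids)):
            raise ValueError(f"source {name!r}: duplicate ids in membership list")
        return cls(name=name, kind="membership", payload={i: 1.0 for i in ids})


@dataclass(frozen=True)
class LabeledRecord:
    record: ProteinRecord
    label: str
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError(f"{self.record.id}: label without provenance")


@dataclass
class LabeledSet:
    """Curated training examples; class assignment is unique per id."""

    records: list[LabeledRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for lr in self.records:
            prev = seen.get(lr.record.id)
            if prev is not None and prev != lr.label:
                raise ValueError(f"{lr.record.id}: conflicting labels {prev}/{lr.label}")
            seen[lr.record.id] = lr.label

    def ids_with_label(self, label: str) -> set[str]:
        return {lr.record.id for lr in self.records if lr.label == label}

    def __len__(self) -> int:
        return len(self.records)


def apply_solubility_thresholds(src: LabelSource) -> dict[str, str]:
    """Threshold a continuous solubility table into partial labels.

    Solubility > 70 -> soluble; < 30 -> aggregation_prone; the [30, 70] band is
    left unlabeled (strict inequalities on both boundaries).
    """
    if src.kind != "continuous-solubility":
        raise ValueError(f"source {src.name!r} is not a solubility table")
    labels: dict[str, str] = {}
    for pid, value in src.payload.items():
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"{src.name}: solubility {value} out of [0,100] for id {pid!r}")
        if value > SOLUBLE_THRESHOLD:
            labels[pid] = SOLUBLE
        elif value < AGGREGATION_THRESHOLD:
            labels[pid] = AGGREGATION_PRONE
    return labels


def merge_labels(
    sol_labels: Mapping[str, str],
    substrates: Sequence[LabelSource],
    sequences: Mapping[str, ProteinRecord],
    sol_source_name: str = "solubility",
) -> LabeledSet:
    """Combine thresholded solubility labels with chaperone-substrate lists.

    Ids appearing in any substrate study are removed from the soluble set; ids
    appearing in >= 2 distinct studies are added to the aggregation-prone set.
    Only ids with an available sequence are emitted; the rest are reported.
    """
    if not substrates:
        raise ValueError("at least one membership source is required")
    for src in substrates:
        if src.kind != "membership":
            raise ValueError(f"source {src.name!r} is not a membership list")

    substrate_ids: dict[str, list[str]] = {}
    for src in substrates:
        for pid in src.payload:
            substrate_ids.setdefault(pid, []).append(src.name)
    any_substrate = set(substrate_ids)
    multi_study = {pid for pid, names in substrate_ids.items() if len(names) >= 2}

    soluble = {p for p, lab in sol_labels.items() if lab == SOLUBLE} - any_substrate
    agg = {p for p, lab in sol_labels.items() if lab == AGGREGATION_PRONE} | multi_study

    records: list[LabeledRecord] = []
    missing: list[str] = []
    for pid in sorted(soluble):
        rec = sequences.get(pid)
        if rec is None:
            missing.append(pid)
            continue
        records.append(LabeledRecord(rec, SOLUBLE, (sol_source_name,)))
    for pid in sorted(agg):
        rec = sequences.get(pid)
        if rec is None:
            missing.append(pid)
            continue
        prov: list[str] = []
        if sol_labels.get(pid) == AGGREGATION_PRONE:
            prov.append(sol_source_name)
        prov.extend(substrate_ids.get(pid, []))
        records.append(LabeledRecord(rec, AGGREGATION_PRONE, tuple(prov)))
    if missing:
        logger.warning("%d labeled ids had no sequence and were dropped: %s",
                       len(missing), missing[:10])
    return LabeledSet(records)


def _aligner() -> Align.PairwiseAligner:
    # match=1, mismatch=0, linear gap -1; identity denominator = alignment columns
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _aligner()


def pairwise_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Global-alignment identity: identical columns / alignment length."""
    seq_a = a.seq if isinstance(a, ProteinRecord) else a
    seq_b = b.seq if isinstance(b, ProteinRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def redundancy_reduce(
    records: Sequence[ProteinRecord], threshold: float = 0.30
) -> list[ProteinRecord]:
    """Greedy incremental clustering at a pairwise-identity threshold.

    Candidates are visited longest-first (ties broken lexicographically by id)
    and kept iff their identity to every previously retained sequence is
    <= threshold. Deterministic; idempotent.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    retained: list[ProteinRecord] = []
    for rec in ordered:
        if all(pairwise_identity(rec, kept) <= threshold for kept in retained):
            retained.append(rec)
    return retained


def reduce_labeled_set(ls: LabeledSet, threshold: float = 0.30) -> LabeledSet:
    """Apply redundancy reduction within each class of a LabeledSet."""
    out: list[LabeledRecord] = []
    by_label: dict[str, list[LabeledRecord]] = {}
    for lr in ls.records:
        by_label.setdefault(lr.label, []).append(lr)
    for label in sorted(by_label):
        group = by_label[label]
        kept_ids = {r.id for r in redundancy_reduce([lr.record for lr in group], threshold)}
        out.extend(lr for lr in group if lr.record.id in kept_ids)
    return LabeledSet(out)


def read_solubility_tsv(path: str | Path, name: str = "solubility") -> LabelSource:
    """TSV with header, columns: id, solubility (percent in [0,100])."""
    payload: dict[str, float] = {}
    lines = Path(path).read_text().strip().splitlines()
    for line in lines[1:]:
        pid, value = line.split("\t")[:2]
        if pid in payload:
            raise ValueError(f"{path}: duplicate id {pid!r}")
        payload[pid] = float(value)
    return LabelSource(name=name, kind="continuous-solubility", payload=payload)


def read_membership_list(path: str | Path, name: str | None = None) -> LabelSource:
    """One protein id per line (no header)."""
    path = Path(path)
    ids = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return LabelSource.membership(name or path.stem, ids)
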