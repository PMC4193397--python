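"""Readers/writers for FASTA, newick and TSV tables, plus basic sequence types.

All downstream analyses join organisms across files (proteome FASTA, GC table,
tree tips, metadata) by exact string match on ``organism_id``; unmatched ids
are reported by the joining code, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical residues, alphabetical. Feature vectors index into this.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues removed during sanitization (ambiguity codes, rare residues, stops).
NON_CANONICAL = set("BZXUO*")

#: Minimum post-sanitization length for proteome scanning; autocorrelation
#: features go up to lag 30 and need len > lag.
MIN_SCAN_LENGTH = 31


class FastaParseError(ValueError):
    """Raised on malformed FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: unique id + canonical amino-acid sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-canonical residues "
                f"{sorted(bad)} (sanitize first)"
            )


@dataclass
class SanitizationReport:
    """Counts of residues dropped and records excluded during sanitization."""

    dropped_residues: int = 0
    dropped_by_code: dict[str, int] = field(default_factory=dict)
    excluded_records: list[str] = field(default_factory=list)


def sanitize_sequence(raw: str, report: SanitizationReport | None = None) -> str:
    """Uppercase ``raw`` and drop non-canonical residues (B, Z, X, U, O, *).

    Unknown letters outside both sets raise; drops are tallied in ``report``.
    """
    seq = raw.upper()
    kept: list[str] = []
    for ch in seq:
        if ch in NON_CANONICAL:
            if report is not None:
                report.dropped_residues += 1
                report.dropped_by_code[ch] = report.dropped_by_code.get(ch, 0) + 1
            continue
        if ch not in AMINO_ACIDS:
            raise FastaParseError(f"unexpected character {ch!r} in sequence")
        kept.append(ch)
    return "".join(kept)


def read_fasta(path: str | Path, sanitize: bool = True) -> list[ProteinRecord]:
    """Read a protein FASTA into ProteinRecords, order preserved.

    Ids are the first whitespace-delimited header token. Lowercase letters are
    uppercased; non-canonical residues are dropped per the sanitization policy,
    with a summary logged. Empty sequences and duplicate ids are errors.
    """
    path = Path(path)
    report = SanitizationReport()
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FastaParseError(f"{path}: entry {i} has an empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if sanitize:
            seq = sanitize_sequence(seq, report)
        if not seq:
            raise FastaParseError(
                f"{path}: entry {rec.id!r} has an empty sequence after sanitization"
            )
        records.append(ProteinRecord(id=rec.id, seq=seq))
    if not records:
        raise FastaParseError(f"{path}: no FASTA entries found")
    if report.dropped_residues:
        logger.warning(
            "%s: dropped %d non-canonical residues (%s)",
            path,
            report.dropped_residues,
            report.dropped_by_code,
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write ProteinRecords as FASTA (round-trips with read_fasta)."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


@dataclass(frozen=True)
class GenomeRecord:
    """Nucleotide composition summary for one genome."""

    organism_id: str
    nucleotide_len: int
    gc_count: int

    def __post_init__(self) -> None:
        if self.nucleotide_len <= 0:
            raise ValueError(f"{self.organism_id}: nucleotide_len must be > 0")
        if not 0 <= self.gc_count <= self.nucleotide_len:
            raise ValueError(f"{self.organism_id}: gc_count out of range")


def genome_record_from_sequence(
    organism_id: str, nt_seq: str, strict: bool = True
) -> GenomeRecord:
    """Summarize a nucleotide sequence, case-insensitively.

    With ``strict=True`` (default) only A/C/G/T count toward total bases;
    other codes are logged. With ``strict=False`` every base counts toward the
    denominator.
    """
    seq = nt_seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    other = len(seq) - acgt
    if other and strict:
        logger.warning(
            "%s: %d non-ACGT bases excluded from GC denominator", organism_id, other
        )
    total = acgt if strict else len(seq)
    return GenomeRecord(organism_id=organism_id, nucleotide_len=total, gc_count=gc)


def gc_content(g: GenomeRecord) -> float:
    """GC content = (G + C) / total bases, in [0, 1]."""
    return g.gc_count / g.nucleotide_len


def read_genome_fasta(
    path: str | Path, organism_id: str | None = None, strict: bool = True
) -> GenomeRecord:
    """Pool all entries of a nucleotide FASTA into one GenomeRecord."""
    path = Path(path)
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise FastaParseError(f"{path}: no FASTA entries found")
    return genome_record_from_sequence(
        organism_id or path.stem, "".join(seqs), strict=strict
    )


class TreeError(ValueError):
    """Raised when a newick tree violates the pipeline's invariants."""


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree with branch lengths.

    Raises TreeError when a non-root edge lacks a branch length (naming the
    node), when tip labels repeat, or when the root is an unrooted-style
    trifurcation-with-no-length (the caller must root the tree first).
    """
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        rooting="default-rooted",
    )
    return validate_tree(tree)


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    if tree.is_rooted is False:
        raise TreeError(
            "tree is explicitly unrooted ([&U]); root it before running the "
            "comparative analyses"
        )
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    missing = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else (node.label or "<internal>")
            missing.append(label)
        elif node.edge.length < 0:
            label = node.taxon.label if node.taxon else (node.label or "<internal>")
            raise TreeError(f"negative branch length at node {label!r}")
    if missing:
        raise TreeError(f"missing branch lengths at nodes: {missing}")
    for node in tree.preorder_internal_node_iter():
        n_children = len(node.child_nodes())
        if n_children == 1 and node.parent_node is not None:
            raise TreeError("internal node with a single child (unifurcation)")
    if len(tree.seed_node.child_nodes()) > 2 and len(tree.leaf_nodes()) > 3:
        logger.info(
            "root has %d children; treated as rooted basal polytomy",
            len(tree.seed_node.child_nodes()),
        )
    return tree
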