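"""Synthetic fixture generators for every pipeline input.

Emulates the study's data artifacts offline: GC-biased proteomes (codon-model
residue frequencies), planted-signal labeled training sets, Yule trees with
correlated Brownian tip traits, and per-genome summary tables. Every generator
is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import dendropy
import numpy as np
from Bio.Data import CodonTable

from .core_io import AMINO_ACIDS, ProteinRecord
from .curation import AGGREGATION_PRONE, SOLUBLE, LabeledRecord, LabeledSet
from .scales import AA_INDEX


@dataclass(frozen=True)
class GenConfig:
    """Knobs for all generators; the seed fully determines every output."""

    seed: int = 0
    n_organisms: int = 60
    proteome_size: int = 100
    length_min: int = 60
    length_mean: int = 150
    length_max: int = 400
    gc_range: tuple[float, float] = (0.25, 0.70)
    # logistic label model: logit = intercept + slope * sum_aa w_aa * comp_aa
    planted_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "G": 1.0, "P": 1.0, "R": 1.0,
                                 "F": -1.0, "I": -1.0, "K": -1.0, "N": -1.0, "Y": -1.0}
    )
    planted_slope: float = 40.0
    planted_intercept: float | None = None  # None: center at the score median
    brownian_rate: float = 1.0
    trait_correlation: float = 0.7

    def __post_init__(self) -> None:
        if self.n_organisms < 1 or self.proteome_size < 1:
            raise ValueError("sizes must be >= 1")
        lo, hi = self.gc_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("gc_range must lie inside (0, 1)")
        if not self.length_min <= self.length_mean <= self.length_max:
            raise ValueError("need length_min <= length_mean <= length_max")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@lru_cache(maxsize=256)
def amino_acid_frequencies(gc: float) -> tuple[float, ...]:
    """Closed-form residue frequencies implied by the standard codon table.

    Each codon's probability is the product of per-position base probabilities
    with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2; stop codons are
    excluded and the distribution renormalized. Returned in AMINO_ACIDS order.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly inside (0, 1)")
    base_p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    table = CodonTable.unambiguous_dna_by_id[1]
    freqs = np.zeros(20)
    for codon, aa in table.forward_table.items():
        p = base_p[codon[0]] * base_p[codon[1]] * base_p[codon[2]]
        freqs[AA_INDEX[aa]] += p
    return tuple(freqs / freqs.sum())


def gen_protein(
    gc: float, length: int, rng: np.random.Generator, pid: str
) -> ProteinRecord:
    freqs = np.asarray(amino_acid_frequencies(round(gc, 6)))
    codes = rng.choice(20, size=length, p=freqs)
    return ProteinRecord(id=pid, seq="".join(AMINO_ACIDS[c] for c in codes))


def _draw_length(cfg: GenConfig, rng: np.random.Generator) -> int:
    # gamma-ish lengths clipped to [min, max]; mean approximately length_mean
    raw = rng.gamma(shape=4.0, scale=cfg.length_mean / 4.0)
    return int(np.clip(round(raw), cfg.length_min, cfg.length_max))


def gen_proteome(
    gc: float, cfg: GenConfig, rng: np.random.Generator | None = None, prefix: str = "p"
) -> list[ProteinRecord]:
    """A proteome of ``cfg.proteome_size`` i.i.d. codon-model proteins at ``gc``."""
    if rng is None:
        rng = cfg.rng()
    return [
        gen_protein(gc, _draw_length(cfg, rng), rng, f"{prefix}{i:05d}")
        for i in range(cfg.proteome_size)
    ]


def planted_score(seq: str, weights: dict[str, float]) -> float:
    """The label model's linear score: sum of weights times residue fractions."""
    counts = {aa: 0 for aa in weights}
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
    return sum(w * counts[aa] / len(seq) for aa, w in weights.items())


def gen_labeled_set(
    cfg: GenConfig,
    n_records: int = 200,
    hard_threshold: bool = False,
) -> LabeledSet:
    """Labeled training sequences with a planted logistic composition signal.

    Sequences are drawn across the configured GC range; the label is Bernoulli
    with logit = slope * (score - center). ``hard_threshold=True`` is the
    infinite-slope limit (perfectly separable in the true features).
    """
    rng = cfg.rng()
    lo, hi = cfg.gc_range
    seqs = []
    for i in range(n_records):
        gc = rng.uniform(lo, hi)
        seqs.append(gen_protein(gc, _draw_length(cfg, rng), rng, f"t{i:05d}"))
    scores = np.array([planted_score(s.seq, cfg.planted_weights) for s in seqs])
    center = (
        cfg.planted_intercept
        if cfg.planted_intercept is not None
        else float(np.median(scores))
    )
    if hard_threshold:
        labels = scores > center
    else:
        p = 1.0 / (1.0 + np.exp(-cfg.planted_slope * (scores - center)))
        labels = rng.uniform(size=n_records) < p
    records = [
        LabeledRecord(
            record=s,
            label=AGGREGATION_PRONE if pos else SOLUBLE,
            provenance=("synthetic",),
        )
        for s, pos in zip(seqs, labels)
    ]
    return LabeledSet(records)


def gen_yule_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Birth-only random tree; every branch length is Exp(1)."""
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    taxa = dendropy.TaxonNamespace([f"org{i:04d}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    leaves = [tree.seed_node]
    while len(leaves) < n_tips:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = parent.new_child(edge_length=float(rng.exponential(1.0)))
            leaves.append(child)
    for leaf, taxon in zip(leaves, taxa):
        leaf.taxon = taxon
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    return tree


def gen_tree_traits(
    n_tips: int,
    rho: float,
    cfg: GenConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dendropy.Tree, dict[str, float], dict[str, float]]:
    """Yule tree plus two Brownian tip traits with generative correlation rho."""
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    cfg = cfg or GenConfig()
    if rng is None:
        rng = cfg.rng()
    tree = gen_yule_tree(n_tips, rng)
    rate = cfg.brownian_rate
    cov = rate * np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    states: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(2)}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = float(node.edge.length or 0.0)
        step = chol @ rng.standard_normal(2) * math.sqrt(bl)
        states[id(node)] = states[id(node.parent_node)] + step
    trait_x: dict[str, float] = {}
    trait_y: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        x, y = states[id(leaf)]
        trait_x[leaf.taxon.label] = float(x)
        trait_y[leaf.taxon.label] = float(y)
    return tree, trait_x, trait_y


def gen_summary_table(cfg: GenConfig) -> list[dict[str, object]]:
    """Per-genome rows in the study's summary-table schema.

    GC drives fAg and fC3 through noisy linear couplings; groEL copy number
    and habitat are drawn with GC-linked propensities.
    """
    rng = cfg.rng()
    lo, hi = cfg.gc_range
    rows = []
    for i in range(cfg.n_organisms):
        gc = float(rng.uniform(lo, hi))
        f_ag = float(np.clip(0.05 + 0.5 * gc + rng.normal(0, 0.03), 0.0, 1.0))
        f_c3 = float(np.clip(f_ag * (0.2 + 0.6 * gc) + rng.normal(0, 0.02), 0.0, f_ag))
        copies = int(rng.poisson(1 + 3 * gc))
        habitat = "symbiont" if rng.uniform() < 0.3 else "free_living"
        rows.append(
            {
                "organism_id": f"org{i:04d}",
                "gc": gc,
                "fAg": f_ag,
                "fC3": f_c3,
                "groel_copies": copies,
                "habitat": habitat,
            }
        )
    return rows
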