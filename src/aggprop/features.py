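"""Deterministic protein-sequence descriptor engine.

Implements the descriptor families used by the shipped 24-feature
classification spec: residue composition, gapped residue-pair composition,
pseudo amino acid composition, Moreau-Broto / Moran / Geary property
autocorrelation, CTD (composition/transition/distribution) over 3-class
physicochemical partitions, quasi-sequence-order, foldability-segment
statistics, and positive-charge distribution.

Conventions
-----------
* Property scales are standardized (zero mean, unit SD over the 20 residues)
  before autocorrelation.
* Features whose lag/gap exceeds the sequence length evaluate to 0 with a
  warning so proteome scans never abort; callers wanting hard failures use
  ``strict=True`` on :func:`extract`.
* Everything is a pure function of the sequence string: same input,
  bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core_io import AMINO_ACIDS, ProteinRecord
from .scales import AA_INDEX, PropertyScale, get_scale, physicochemical_distance_matrix

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# residue groupings for CTD descriptors
# --------------------------------------------------------------------------

#: 3-class partitions used by CTD descriptors. Classes are 1-indexed in the
#: public API, matching descriptor-naming convention.
CTD_GROUPINGS: dict[str, tuple[str, str, str]] = {
    # polarizability 0-0.108 / 0.128-0.186 / 0.219-0.409
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    # normalized van der Waals volume 0-2.78 / 2.95-4.0 / 4.03-8.08
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    # net side-chain charge at neutral pH (positive / negative / neutral)
    "charge": ("KRH", "DE", "ACFGILMNPQSTVWY"),
}

DISTRIBUTION_POINTS = ("first", "25%", "50%", "75%", "100%")

_seq_cache: dict[str, np.ndarray] = {}


def _codes(seq: str) -> np.ndarray:
    out = _seq_cache.get(seq)
    if out is None:
        out = np.fromiter((AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
        if len(_seq_cache) > 4096:
            _seq_cache.clear()
        _seq_cache[seq] = out
    return out


def _seq_of(p: ProteinRecord | str) -> str:
    return p.seq if isinstance(p, ProteinRecord) else p


# --------------------------------------------------------------------------
# descriptor families
# --------------------------------------------------------------------------


def aa_composition(p: ProteinRecord | str) -> np.ndarray:
    """Fractions of the 20 residues (alphabetical order); sums to 1."""
    seq = _seq_of(p)
    if not seq:
        raise ValueError("empty sequence")
    counts = np.bincount(_codes(seq), minlength=20).astype(float)
    return counts / len(seq)


def gapped_pair_composition(
    p: ProteinRecord | str, a: str, b: str, gap: int
) -> float:
    """Fraction of positions i with seq[i]==a and seq[i+gap+1]==b.

    Denominator is the number of windows, ``len - gap - 1``. Sequences too
    short for one window return 0 with a warning.
    """
    seq = _seq_of(p)
    if gap < 0:
        raise ValueError("gap must be >= 0")
    n_windows = len(seq) - gap - 1
    if n_windows < 1:
        logger.warning("sequence of length %d too short for gap %d; value 0", len(seq), gap)
        return 0.0
    offset = gap + 1
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits = np.count_nonzero((arr[:-offset] == ord(a)) & (arr[offset:] == ord(b)))
    return hits / n_windows


#: Property triple used for PseAAC sequence-order correlation factors.
PSEAAC_PROPERTIES = ("hydrophobicity", "hydrophilicity", "volume")


def pseaac(p: ProteinRecord | str, lam: int = 30, w: float = 0.05) -> np.ndarray:
    """Pseudo amino acid composition: 20 residue terms + lam order factors.

    theta_d averages, over residue pairs d apart, the mean squared difference
    of standardized property values (hydrophobicity, hydrophilicity, volume).
    Components are non-negative and sum to 1.
    """
    seq = _seq_of(p)
    L = len(seq)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam >= L:
        raise ValueError(f"lam={lam} >= sequence length {L}")
    freqs = aa_composition(seq)
    codes = _codes(seq)
    props = np.stack([get_scale(n).standardized for n in PSEAAC_PROPERTIES], axis=1)
    vals = props[codes]  # L x 3
    thetas = np.empty(lam)
    for d in range(1, lam + 1):
        diff = vals[d:] - vals[:-d]
        thetas[d - 1] = np.mean((diff**2).mean(axis=1))
    denom = 1.0 + w * thetas.sum()
    return np.concatenate([freqs / denom, w * thetas / denom])


AutocorrKind = Literal["MoreauBroto", "Moran", "Geary"]


def autocorrelation(
    p: ProteinRecord | str, kind: AutocorrKind, scale: PropertyScale | str, lag: int
) -> float:
    """Property autocorrelation at ``lag`` on the standardized scale.

    MoreauBroto: mean of P_i * P_{i+lag}.
    Moran: covariance form normalized by the sequence property variance.
    Geary: squared-difference form normalized by the (n-1) variance.

    Sequences with len <= lag return 0 with a warning; zero sequence variance
    (homopolymers) returns 0 for Moran/Geary by convention.
    """
    seq = _seq_of(p)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    L = len(seq)
    if L <= lag:
        logger.warning("sequence of length %d too short for lag %d; value 0", L, lag)
        return 0.0
    if isinstance(scale, str):
        scale = get_scale(scale)
    vals = scale.values_for(seq)
    if kind == "MoreauBroto":
        return float(np.dot(vals[:-lag], vals[lag:]) / (L - lag))
    mean = vals.mean()
    centered = vals - mean
    if kind == "Moran":
        den = float(np.dot(centered, centered)) / L
        if den == 0.0:
            logger.warning("zero sequence variance; Moran autocorrelation set to 0")
            return 0.0
        num = float(np.dot(centered[:-lag], centered[lag:])) / (L - lag)
        return num / den
    if kind == "Geary":
        den = float(np.dot(centered, centered)) / (L - 1)
        if den == 0.0:
            logger.warning("zero sequence variance; Geary autocorrelation set to 0")
            return 0.0
        diff = vals[:-lag] - vals[lag:]
        num = float(np.dot(diff, diff)) / (2 * (L - lag))
        return num / den
    raise ValueError(f"unknown autocorrelation kind {kind!r}")


def _group_mask(seq: str, grouping: str, group: int) -> np.ndarray:
    members = CTD_GROUPINGS[grouping][group - 1]
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = np.zeros(len(seq), dtype=bool)
    for ch in members:
        mask |= arr == ord(ch)
    return mask


def ctd_composition(p: ProteinRecord | str, grouping: str, group: int) -> float:
    """Fraction of residues in the given class of a 3-class partition."""
    seq = _seq_of(p)
    if not seq:
        raise ValueError("empty sequence")
    return float(_group_mask(seq, grouping, group).mean())


def ctd_transition(p: ProteinRecord | str, grouping: str, ga: int, gb: int) -> float:
    """Normalized count of adjacent residue pairs crossing classes ga<->gb."""
    seq = _seq_of(p)
    if len(seq) < 2:
        return 0.0
    ma = _group_mask(seq, grouping, ga)
    mb = _group_mask(seq, grouping, gb)
    cross = (ma[:-1] & mb[1:]) | (mb[:-1] & ma[1:])
    return float(np.count_nonzero(cross) / (len(seq) - 1))


def ctd_distribution(
    p: ProteinRecord | str, grouping: str, group: int, point: str
) -> float:
    """Distribution descriptor: percent position of a group-occurrence quantile.

    ``point`` is one of first/25%/50%/75%/100%. The k-th occurrence used for
    quantile q is ceil(q * n_occurrences); the value is its 1-based position
    divided by the sequence length, times 100. Absent group -> 0, logged.
    """
    seq = _seq_of(p)
    if point not in DISTRIBUTION_POINTS:
        raise ValueError(f"point must be one of {DISTRIBUTION_POINTS}")
    positions = np.flatnonzero(_group_mask(seq, grouping, group)) + 1  # 1-based
    n = len(positions)
    if n == 0:
        logger.warning("group %d of %r absent from sequence; distribution 0", group, grouping)
        return 0.0
    if point == "first":
        k = 1
    else:
        q = int(point.rstrip("%")) / 100.0
        k = max(1, math.ceil(q * n))
    return float(positions[k - 1] / len(seq) * 100.0)


def quasi_sequence_order(
    p: ProteinRecord | str,
    maxlag: int = 30,
    w: float = 0.1,
    dmat: np.ndarray | None = None,
) -> np.ndarray:
    """Quasi-sequence-order vector: 20 residue terms + maxlag coupling terms.

    tau_d = sum_i d(seq_i, seq_{i+d})^2 on the physicochemical distance
    matrix; the full (20+maxlag)-vector is normalized to sum 1.
    """
    seq = _seq_of(p)
    L = len(seq)
    if maxlag < 1:
        raise ValueError("maxlag must be >= 1")
    if maxlag >= L:
        raise ValueError(f"maxlag={maxlag} >= sequence length {L}")
    if dmat is None:
        dmat = physicochemical_distance_matrix()
    codes = _codes(seq)
    taus = np.empty(maxlag)
    for d in range(1, maxlag + 1):
        taus[d - 1] = float((dmat[codes[:-d], codes[d:]] ** 2).sum())
    freqs = aa_composition(seq)
    denom = 1.0 + w * taus.sum()
    return np.concatenate([freqs / denom, w * taus / denom])


# FoldIndex-style windowed foldability: 2.785 * <H> - |<q>| - 1.151, where H is
# hydrophobicity rescaled to [0,1] and q the mean net charge (K,R = +1; D,E = -1).
_FOLD_A, _FOLD_B = 2.785, 1.151


def foldindex_profile(p: ProteinRecord | str, window: int = 16) -> np.ndarray:
    """Windowed foldability index, one value per window position."""
    seq = _seq_of(p)
    L = len(seq)
    if window < 1:
        raise ValueError("window must be >= 1")
    if L < window:
        logger.warning(
            "sequence of length %d shorter than window %d; using one whole-sequence window",
            L,
            window,
        )
        window = L
    kd = get_scale("hydrophobicity").raw_array
    hydro01 = (kd - kd.min()) / (kd.max() - kd.min())  # KD rescaled to [0,1]
    charge = np.zeros(20)
    for ch, q in (("K", 1.0), ("R", 1.0), ("D", -1.0), ("E", -1.0)):
        charge[AA_INDEX[ch]] = q
    codes = _codes(seq)
    h = hydro01[codes]
    q = charge[codes]
    kernel = np.ones(window) / window
    mean_h = np.convolve(h, kernel, mode="valid")
    mean_q = np.convolve(q, kernel, mode="valid")
    return _FOLD_A * mean_h - np.abs(mean_q) - _FOLD_B


def _run_lengths(mask: np.ndarray) -> list[int]:
    runs, current = [], 0
    for flag in mask:
        if flag:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def foldindex_features(p: ProteinRecord | str, window: int = 16) -> dict[str, float]:
    """Segment statistics of the foldability profile.

    Positions with index > 0 are folded; segments are maximal folded runs over
    the scored window positions.
    """
    profile = foldindex_profile(p, window)
    runs = _run_lengths(profile > 0)
    n_scored = len(profile)
    return {
        "avg_folded_segment_length": float(np.mean(runs)) if runs else 0.0,
        "n_folded_segments": float(len(runs)),
        "longest_folded_segment": float(max(runs)) if runs else 0.0,
        "folded_fraction": float(sum(runs) / n_scored) if n_scored else 0.0,
    }


def charge_distribution(p: ProteinRecord | str) -> dict[str, float]:
    """CTD-style distribution points of positively charged residues {K,R,H}."""
    return {
        point: ctd_distribution(p, "charge", 1, point) for point in DISTRIBUTION_POINTS
    }


# --------------------------------------------------------------------------
# feature specs
# --------------------------------------------------------------------------

FAMILIES = frozenset(
    {
        "composition",
        "gapped_pair",
        "pseaac",
        "autocorrelation",
        "ctd",
        "qso",
        "foldindex",
        "charge_distribution",
    }
)


@dataclass(frozen=True)
class Feature:
    """One named descriptor: family + complete parameter set."""

    feature_id: str
    family: str
    params: tuple[tuple[str, object], ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered, uniquely-named feature list; hashable for model provenance."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate feature ids in spec")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"feature_id": f.feature_id, "family": f.family, "params": f.param_dict}
                for f in self.features
            ],
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSpec":
        rows = json.loads(text)
        return cls(
            tuple(
                Feature(
                    feature_id=r["feature_id"],
                    family=r["family"],
                    params=tuple(sorted(r["params"].items())),
                )
                for r in rows
            )
        )

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _f(fid: str, family: str, **params: object) -> Feature:
    return Feature(feature_id=fid, family=family, params=tuple(sorted(params.items())))


def default_spec() -> FeatureSpec:
    """The shipped 24-feature spec used by the aggregation/GroEL classifiers."""
    mb, mrn, gry = "MoreauBroto", "Moran", "Geary"
    return FeatureSpec(
        (
            _f("SW_SOC2", "qso", component="tau", d=2, maxlag=30, w=0.1),
            _f("PPR", "charge_distribution", point="50%"),
            _f("H(8)M", "gapped_pair", a="H", b="M", gap=8),
            _f("M-B(Hydr)1", "autocorrelation", kind=mb, scale="hydrophobicity", lag=1),
            _f("PseAAC_T1_3", "pseaac", residue="D", lam=30, w=0.05),
            _f("PseAAC_T1_5", "pseaac", residue="F", lam=30, w=0.05),
            _f("FI_16_psavgl", "foldindex", window=16, stat="avg_folded_segment_length"),
            _f("PseAAC_T1_4", "pseaac", residue="E", lam=30, w=0.05),
            _f("Dstrbu_Pol_2:3", "ctd", part="distribution", grouping="polarizability", group=2, point="50%"),
            _f("M-B(mutblty)6", "autocorrelation", kind=mb, scale="mutability", lag=6),
            _f("T", "composition", residue="T"),
            _f("Mrn(vlum)27", "autocorrelation", kind=mrn, scale="volume", lag=27),
            _f("Mrn(Polar)22", "autocorrelation", kind=mrn, scale="polarizability", lag=22),
            _f("M-B(mutblty)9", "autocorrelation", kind=mb, scale="mutability", lag=9),
            _f("Geary(sterc)4", "autocorrelation", kind=gry, scale="steric", lag=4),
            _f("M-B(mutblty)24", "autocorrelation", kind=mb, scale="mutability", lag=24),
            _f("M-B(Hydr)12", "autocorrelation", kind=mb, scale="hydrophobicity", lag=12),
            _f("Mrn(RsdAcc)24", "autocorrelation", kind=mrn, scale="asa_tripeptide", lag=24),
            _f("Mrn(Hydr)23", "autocorrelation", kind=mrn, scale="hydrophobicity", lag=23),
            _f("Geary(Free)13", "autocorrelation", kind=gry, scale="free_energy", lag=13),
            _f("Comp_Vol_2", "ctd", part="composition", grouping="vdw_volume", group=2),
            _f("Geary(vlum)20", "autocorrelation", kind=gry, scale="volume", lag=20),
            _f("Geary(Free)14", "autocorrelation", kind=gry, scale="free_energy", lag=14),
            _f("M-B(vlum)30", "autocorrelation", kind=mb, scale="volume", lag=30),
        )
    )


@dataclass(frozen=True)
class FeatureVector:
    """Descriptor values for one protein, aligned to a FeatureSpec."""

    protein_id: str
    values: tuple[float, ...]
    spec_digest: str

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError(f"non-finite feature value for {self.protein_id!r}")


def _compute_feature(seq: str, feat: Feature, strict: bool) -> float:
    p = feat.param_dict
    L = len(seq)
    if feat.family == "composition":
        return float(aa_composition(seq)[AA_INDEX[p["residue"]]])
    if feat.family == "gapped_pair":
        val = gapped_pair_composition(seq, p["a"], p["b"], int(p["gap"]))
        if strict and L <= int(p["gap"]) + 1:
            raise ValueError(f"sequence too short for feature {feat.feature_id}")
        return val
    if feat.family == "pseaac":
        lam = int(p["lam"])
        if lam >= L:
            if strict:
                raise ValueError(f"sequence too short for feature {feat.feature_id}")
            logger.warning("reducing pseaac lam to %d for length-%d sequence", L - 1, L)
            lam = L - 1
        vec = pseaac(seq, lam=lam, w=float(p["w"]))
        return float(vec[AA_INDEX[p["residue"]]])
    if feat.family == "autocorrelation":
        val = autocorrelation(seq, p["kind"], p["scale"], int(p["lag"]))
        if strict and L <= int(p["lag"]):
            raise ValueError(f"sequence too short for feature {feat.feature_id}")
        return val
    if feat.family == "ctd":
        if p["part"] == "composition":
            return ctd_composition(seq, p["grouping"], int(p["group"]))
        if p["part"] == "transition":
            return ctd_transition(seq, p["grouping"], int(p["ga"]), int(p["gb"]))
        if p["part"] == "distribution":
            return ctd_distribution(seq, p["grouping"], int(p["group"]), p["point"])
        raise ValueError(f"unknown ctd part {p['part']!r}")
    if feat.family == "qso":
        maxlag = int(p["maxlag"])
        if maxlag >= L:
            if strict:
                raise ValueError(f"sequence too short for feature {feat.feature_id}")
            logger.warning("reducing qso maxlag to %d for length-%d sequence", L - 1, L)
            maxlag = L - 1
        vec = quasi_sequence_order(seq, maxlag=maxlag, w=float(p["w"]))
        if p["component"] == "tau":
            d = int(p["d"])
            return float(vec[20 + d - 1]) if d <= maxlag else 0.0
        return float(vec[AA_INDEX[p["component"]]])
    if feat.family == "foldindex":
        return foldindex_features(seq, window=int(p["window"]))[p["stat"]]
    if feat.family == "charge_distribution":
        return charge_distribution(seq)[p["point"]]
    raise ValueError(f"unknown feature family {feat.family!r}")


def extract(
    p: ProteinRecord | str, spec: FeatureSpec | None = None, strict: bool = False
) -> FeatureVector:
    """Compute every feature in ``spec`` for one protein.

    Total over the curated length policy: short-sequence features degrade to 0
    (or reduced lag) with warnings unless ``strict=True``. Never emits
    NaN/Inf; empty sequences are a hard error.
    """
    if spec is None:
        spec = default_spec()
    seq = _seq_of(p)
    if not seq:
        raise ValueError("empty sequence")
    values = tuple(_compute_feature(seq, feat, strict) for feat in spec.features)
    pid = p.id if isinstance(p, ProteinRecord) else ""
    return FeatureVector(protein_id=pid, values=values, spec_digest=spec.digest())


def extract_matrix(
    records: Sequence[ProteinRecord],
    spec: FeatureSpec | None = None,
    strict: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Feature matrix (n_proteins x n_features) for a batch of proteins."""
    if spec is None:
        spec = default_spec()
    vectors = [extract(r, spec, strict=strict) for r in records]
    ids = [v.protein_id for v in vectors]
    return ids, np.array([v.values for v in vectors], dtype=float)
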