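"""Amino-acid property scales and derived physicochemical distance matrix.

Scales ship as a versioned TSV data file (``data/property_scales.tsv``) and are
exposed both raw and standardized (zero mean, unit SD over the 20 residues).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core_io import AMINO_ACIDS

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class PropertyScale:
    """A named residue->value map, stored raw and standardized."""

    name: str
    raw: tuple[float, ...]  # aligned to AMINO_ACIDS order

    @property
    def raw_array(self) -> np.ndarray:
        return np.asarray(self.raw, dtype=float)

    @property
    def standardized(self) -> np.ndarray:
        v = self.raw_array
        return (v - v.mean()) / v.std()  # population SD over the 20 residues

    def values_for(self, seq: str, standardized: bool = True) -> np.ndarray:
        table = self.standardized if standardized else self.raw_array
        idx = np.fromiter((AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
        return table[idx]


@lru_cache(maxsize=1)
def load_scales() -> dict[str, PropertyScale]:
    """Load every property scale from the package data file."""
    ref = importlib.resources.files("aggprop.data").joinpath("property_scales.tsv")
    lines = ref.read_text().strip().splitlines()
    header = lines[0].split("\t")
    names = header[1:]
    values: dict[str, dict[str, float]] = {n: {} for n in names}
    for line in lines[1:]:
        parts = line.split("\t")
        residue = parts[0]
        for name, val in zip(names, parts[1:]):
            values[name][residue] = float(val)
    scales = {}
    for name in names:
        if set(values[name]) != set(AMINO_ACIDS):
            raise ValueError(f"scale {name!r} does not cover the 20 residues")
        scales[name] = PropertyScale(
            name=name, raw=tuple(values[name][aa] for aa in AMINO_ACIDS)
        )
    return scales


def get_scale(name: str) -> PropertyScale:
    scales = load_scales()
    if name not in scales:
        raise KeyError(f"unknown property scale {name!r}; have {sorted(scales)}")
    return scales[name]


@lru_cache(maxsize=1)
def physicochemical_distance_matrix() -> np.ndarray:
    """20x20 inter-residue distance matrix for quasi-sequence-order descriptors.

    Euclidean distance over standardized hydrophobicity, hydrophilicity and
    residue volume — the property triple of the Schneider–Wrede /
    pseudo-amino-acid-composition lineage. d(a,a) = 0, symmetric.
    """
    props = np.stack(
        [
            get_scale("hydrophobicity").standardized,
            get_scale("hydrophilicity").standardized,
            get_scale("volume").standardized,
        ],
        axis=1,
    )
    diff = props[:, None, :] - props[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))
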