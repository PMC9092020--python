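"""Inter-residue geometry: distances, true contact maps, separation classes.

Two residues are in contact when the Euclidean distance between their
representative atoms (C-beta; C-alpha for glycine) is strictly less than a
threshold gamma, 8 angstroms by default. Pairs are binned by sequence
separation |i - j|: short range 6-11, medium range 12-23, long range >= 24;
pairs closer than 6 are excluded from evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rcmpm.io_formats import ResidueChain

DEFAULT_GAMMA = 8.0

#: Inclusive |i - j| bounds of the CASP separation classes.
SEPARATION_RANGES: dict[str, tuple[int, float]] = {
    "short": (6, 11),
    "medium": (12, 23),
    "long": (24, np.inf),
    # combined bin used when medium- and long-range pairs are scored together
    "medium+long": (12, np.inf),
}


@dataclass
class ContactMap:
    """L x L binary contact labels at distance threshold ``gamma``."""

    labels: np.ndarray
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2 or self.labels.shape[0] != self.labels.shape[1]:
            raise ValueError(f"contact map is not square: {self.labels.shape}")
        if not np.array_equal(self.labels, self.labels.T):
            raise ValueError("contact map is not symmetric")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("contact labels must be 0/1")

    @property
    def L(self) -> int:
        return self.labels.shape[0]


def cbeta_distance(chain: ResidueChain, i: int, j: int) -> float:
    """Euclidean distance between the representative atoms of residues i and j."""
    if not (0 <= i < chain.L and 0 <= j < chain.L):
        raise IndexError(f"residue index out of range for L={chain.L}")
    return float(np.linalg.norm(chain.coords[i] - chain.coords[j]))


def distance_matrix(chain: ResidueChain) -> np.ndarray:
    """All-pairs representative-atom distance matrix (L x L, angstroms)."""
    diff = chain.coords[:, None, :] - chain.coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def true_contact_map(chain: ResidueChain, gamma: float = DEFAULT_GAMMA) -> ContactMap:
    """Ground-truth contacts: distance strictly below ``gamma``.

    The strict inequality means a pair at exactly ``gamma`` is a
    non-contact. The diagonal is 1 (distance zero).
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    labels = (distance_matrix(chain) < gamma).astype(np.int8)
    return ContactMap(labels, gamma=gamma)


def separation_class(i: int, j: int) -> str:
    """CASP separation class of the pair: excluded/short/medium/long."""
    s = abs(i - j)
    if s < 6:
        return "excluded"
    if s <= 11:
        return "short"
    if s <= 23:
        return "medium"
    return "long"


def separation_mask(L: int, range_name: str) -> np.ndarray:
    """Boolean L x L mask of pairs whose |i - j| falls in the named class."""
    if range_name not in SEPARATION_RANGES:
        raise ValueError(
            f"unknown separation range {range_name!r}; "
            f"expected one of {sorted(SEPARATION_RANGES)}"
        )
    lo, hi = SEPARATION_RANGES[range_name]
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    return (sep >= lo) & (sep <= hi)
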