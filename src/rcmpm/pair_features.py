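"""Pairwise feature channels: rough-map scores, MI, APC-corrected MI, contact potential.

Column statistics are unweighted row frequencies over a 21-symbol alphabet
(20 amino acids plus gap; unknown residues count as gap), with no
pseudocounts. Mutual information is in nats. The average product correction
(APC) subtracts the product of a column pair's mean off-diagonal MI row sums
over the total off-diagonal MI, suppressing the shared phylogenetic and
entropy background that inflates raw MI.

The bundled default contact-potential table is a synthetic quasi-chemical
surrogate derived from the Kyte-Doolittle hydrophobicity scale
(e_ab = -(h_a + h_b)/9, so hydrophobic pairs are favourable); any symmetric
20x20 table in the same text layout can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from rcmpm.io_formats import AMINO_ACIDS, FormatError, MSA, ScoreMatrix

#: Index of the gap symbol in the 21-letter counting alphabet.
GAP_INDEX = 20
_AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}


@dataclass
class ColumnStats:
    """Joint and marginal symbol frequencies of one column pair."""

    p_i: np.ndarray  # (21,)
    p_j: np.ndarray  # (21,)
    p_ij: np.ndarray  # (21, 21)

    def __post_init__(self) -> None:
        for name, arr, total in (
            ("p_i", self.p_i, 1.0),
            ("p_j", self.p_j, 1.0),
            ("p_ij", self.p_ij, 1.0),
        ):
            if abs(arr.sum() - total) > 1e-9:
                raise ValueError(f"{name} sums to {arr.sum()}, expected {total}")
        if np.abs(self.p_ij.sum(axis=1) - self.p_i).max() > 1e-9:
            raise ValueError("p_ij row marginal does not match p_i")
        if np.abs(self.p_ij.sum(axis=0) - self.p_j).max() > 1e-9:
            raise ValueError("p_ij column marginal does not match p_j")


@dataclass
class PotentialTable:
    """Symmetric 20 x 20 per-pair statistical contact energies."""

    energies: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (20, 20):
            raise ValueError(f"potential table must be 20x20, got {self.energies.shape}")
        if not np.isfinite(self.energies).all():
            raise ValueError("potential table has non-finite entries")
        if np.abs(self.energies - self.energies.T).max() > 1e-9:
            raise ValueError("potential table is not symmetric")


@dataclass
class PairFeatureTensor:
    """L x L x 5 pairwise features in the fixed channel order
    [rough map A, rough map B, MI, APC MI, contact potential]."""

    channels: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[2] != 5:
            raise ValueError(f"pair tensor must be L x L x 5, got {self.channels.shape}")
        if self.channels.shape[0] != self.channels.shape[1]:
            raise ValueError("pair tensor first two axes must match")

    @property
    def L(self) -> int:
        return self.channels.shape[0]


def encode_msa(msa: MSA) -> np.ndarray:
    """Integer-encode an MSA: amino acids 0..19, gap/unknown 20. Shape (rows, cols)."""
    out = np.empty((msa.rows, msa.cols), dtype=np.int8)
    for r, seq in enumerate(msa.sequences):
        out[r] = [_AA_INDEX.get(ch, GAP_INDEX) for ch in seq]
    return out


def column_stats(msa: MSA, i: int, j: int) -> ColumnStats:
    """Unweighted symbol frequencies of columns i and j (gap is a 21st symbol)."""
    if not (0 <= i < msa.cols and 0 <= j < msa.cols):
        raise IndexError(f"column index out of range for cols={msa.cols}")
    enc = encode_msa(msa)
    ci, cj = enc[:, i], enc[:, j]
    p_ij = np.bincount(ci.astype(int) * 21 + cj, minlength=441).reshape(21, 21)
    p_ij = p_ij / msa.rows
    return ColumnStats(p_i=p_ij.sum(axis=1), p_j=p_ij.sum(axis=0), p_ij=p_ij)


def mutual_information(stats: ColumnStats) -> float:
    """MI of a column pair in nats; zero-probability terms are skipped."""
    mask = stats.p_ij > 0
    pij = stats.p_ij[mask]
    denom = np.outer(stats.p_i, stats.p_j)[mask]
    return float(np.sum(pij * np.log(pij / denom)))


def mi_matrix(msa: MSA) -> np.ndarray:
    """All-pairs MI matrix (L x L, symmetric, diagonal = column entropy)."""
    enc = encode_msa(msa).astype(int)
    L = msa.cols
    rows = msa.rows
    mi = np.zeros((L, L))
    # per-column marginals
    marg = np.zeros((L, 21))
    for i in range(L):
        marg[i] = np.bincount(enc[:, i], minlength=21) / rows
    for i in range(L):
        for j in range(i, L):
            pij = np.bincount(enc[:, i] * 21 + enc[:, j], minlength=441)
            pij = pij.reshape(21, 21) / rows
            mask = pij > 0
            val = float(
                np.sum(pij[mask] * np.log(pij[mask] / np.outer(marg[i], marg[j])[mask]))
            )
            mi[i, j] = mi[j, i] = val
    return mi


def apc_matrix(mi: np.ndarray) -> np.ndarray:
    """Average-product-corrected MI: MI_ij - (S_i * S_j) / S_total.

    Row sums S_i, S_j and the total S exclude the diagonal. If the total
    off-diagonal MI is zero the correction is defined as zero. The output
    diagonal is zero.
    """
    mi = np.asarray(mi, dtype=float)
    L = mi.shape[0]
    if mi.ndim != 2 or mi.shape[1] != L:
        raise ValueError("MI matrix must be square")
    if L < 2:
        raise ValueError("APC requires L >= 2")
    off = mi - np.diag(np.diag(mi))
    row_sums = off.sum(axis=1)
    total = off.sum()
    if total == 0.0:
        return np.zeros_like(mi)
    corrected = off - np.outer(row_sums, row_sums) / total
    np.fill_diagonal(corrected, 0.0)
    return corrected


def load_potential_table(path: str | Path | None = None) -> PotentialTable:
    """Load a 20 x 20 potential table (header row of one-letter codes).

    With no path, loads the bundled synthetic hydrophobicity-derived table.
    Rows/columns are re-ordered to the package's canonical alphabet.
    """
    if path is None:
        ref = resources.files("rcmpm").joinpath("data/contact_potential.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    if sorted("".join(header)) != sorted(AMINO_ACIDS):
        raise FormatError("potential table header must list the 20 one-letter codes")
    order = [_AA_INDEX["".join(header)[k]] for k in range(20)]
    raw = np.array([[float(x) for x in ln.split()] for ln in lines[1:]])
    if raw.shape != (20, 20):
        raise FormatError(f"potential table body must be 20x20, got {raw.shape}")
    energies = np.empty((20, 20))
    for a in range(20):
        for b in range(20):
            energies[order[a], order[b]] = raw[a, b]
    return PotentialTable(energies)


def contact_potential(msa: MSA, table: PotentialTable, i: int, j: int) -> float:
    """Mean contact-potential term over rows with amino acids in both columns.

    Rows where either column holds a gap or unknown are skipped; if every
    row is skipped the potential is 0.
    """
    enc = encode_msa(msa).astype(int)
    ci, cj = enc[:, i], enc[:, j]
    ok = (ci < 20) & (cj < 20)
    if not ok.any():
        return 0.0
    return float(table.energies[ci[ok], cj[ok]].mean())


def potential_matrix(msa: MSA, table: PotentialTable | None = None) -> np.ndarray:
    """All-pairs averaged contact potential (L x L, symmetric)."""
    if table is None:
        table = load_potential_table()
    enc = encode_msa(msa).astype(int)
    L = msa.cols
    pot = np.zeros((L, L))
    for i in range(L):
        ci = enc[:, i]
        for j in range(i, L):
            cj = enc[:, j]
            ok = (ci < 20) & (cj < 20)
            if ok.any():
                val = float(table.energies[ci[ok], cj[ok]].mean())
            else:
                val = 0.0
            pot[i, j] = pot[j, i] = val
    return pot


def assemble_pair_tensor(
    rough_a: ScoreMatrix,
    rough_b: ScoreMatrix,
    mi: np.ndarray,
    apc_mi: np.ndarray,
    pot: np.ndarray,
) -> PairFeatureTensor:
    """Stack the five pairwise channels in the model's fixed order."""
    mats = [rough_a.values, rough_b.values, np.asarray(mi), np.asarray(apc_mi), np.asarray(pot)]
    L = mats[0].shape[0]
    for m in mats:
        if m.shape != (L, L):
            raise ValueError(f"channel shape {m.shape} does not match ({L}, {L})")
    return PairFeatureTensor(np.stack(mats, axis=-1))
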