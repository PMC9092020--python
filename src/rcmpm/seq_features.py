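"""Per-residue sequence features: PSSM + secondary structure + solvent accessibility.

The model consumes an L x 26 tensor per protein, columns 0-19 the PSSM
log-odds, 20-22 the 3-class secondary-structure channels (helix H, strand
E, coil C) and 23-25 the 3-class solvent-accessibility channels (buried,
medium, exposed), in that fixed order.

A real PSI-BLAST ASCII PSSM (via :mod:`rcmpm.io_formats`) is preferred when
available; :func:`pssm_from_msa` provides an offline stand-in computed from
the alignment itself with pseudocount-regularized log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from rcmpm.io_formats import FormatError, MSA, PSSMProfile
from rcmpm.pair_features import encode_msa

SS_CLASSES = ("H", "E", "C")
SA_CLASSES = ("B", "M", "E")
_SA_WORDS = {"BURIED": "B", "MEDIUM": "M", "EXPOSED": "E"}


@dataclass
class StructureProfile:
    """3-class secondary-structure and solvent-accessibility rows (each sums to 1)."""

    ss: np.ndarray  # (L, 3) helix/strand/coil
    sa: np.ndarray  # (L, 3) buried/medium/exposed

    def __post_init__(self) -> None:
        self.ss = np.asarray(self.ss, dtype=float)
        self.sa = np.asarray(self.sa, dtype=float)
        for name, arr in (("ss", self.ss), ("sa", self.sa)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must be L x 3, got {arr.shape}")
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if np.abs(arr.sum(axis=1) - 1).max() > 1e-6:
                raise ValueError(f"{name} rows must sum to 1")
        if self.ss.shape[0] != self.sa.shape[0]:
            raise ValueError("ss and sa lengths differ")

    @property
    def L(self) -> int:
        return self.ss.shape[0]


@dataclass
class SeqFeatureTensor:
    """L x 26 per-residue features in the fixed order [PSSM | SS | SA]."""

    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != 26:
            raise ValueError(f"sequence tensor must be L x 26, got {self.features.shape}")
        if not np.isfinite(self.features).all():
            raise ValueError("non-finite sequence features")

    @property
    def L(self) -> int:
        return self.features.shape[0]


def pssm_from_msa(
    msa: MSA, pseudocount: float = 1.0, background: np.ndarray | None = None
) -> PSSMProfile:
    """Pseudocount log-odds profile computed from the alignment.

    Per column, score_a = ln( ((count_a + c * q_a) / (rows + c)) / q_a )
    with pseudocount mass c and background q. Gaps are excluded from the
    counts and the per-column row total is reduced accordingly, so an
    all-gap column scores 0 for every amino acid.
    """
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,):
        raise ValueError("background must have 20 entries")
    if (background <= 0).any():
        raise ValueError("background frequencies must be positive")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    enc = encode_msa(msa).astype(int)
    scores = np.empty((msa.cols, 20))
    for i in range(msa.cols):
        col = enc[:, i]
        col = col[col < 20]
        counts = np.bincount(col, minlength=20)[:20]
        freqs = (counts + pseudocount * background) / (len(col) + pseudocount)
        scores[i] = np.log(freqs / background)
    return PSSMProfile(scores)


def encode_three_class(
    labels_or_probs, classes: tuple[str, str, str]
) -> np.ndarray:
    """Turn per-residue 3-class labels (one-hot) or probability rows (normalized)
    into an L x 3 matrix."""
    if isinstance(labels_or_probs, str):
        labels_or_probs = list(labels_or_probs)
    first = labels_or_probs[0] if len(labels_or_probs) else None
    if isinstance(first, str):
        rows = []
        for lab in labels_or_probs:
            lab = _SA_WORDS.get(lab.upper(), lab.upper())
            if lab not in classes:
                raise ValueError(f"unknown label {lab!r}; expected one of {classes}")
            rows.append([1.0 if c == lab else 0.0 for c in classes])
        return np.array(rows)
    probs = np.asarray(labels_or_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError(f"probability input must be L x 3, got {probs.shape}")
    if (probs < 0).any():
        raise ValueError("negative class probability")
    sums = probs.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("each probability row needs positive mass")
    return probs / sums[:, None]


def encode_structure_profile(ss_input, sa_input) -> StructureProfile:
    """Build a StructureProfile from labels or probability rows for SS and SA."""
    return StructureProfile(
        ss=encode_three_class(ss_input, SS_CLASSES),
        sa=encode_three_class(sa_input, SA_CLASSES),
    )


def parse_profile(path: str | Path) -> StructureProfile:
    """Read a per-residue profile file.

    One line per residue, either two bare labels ``H B`` or labels with
    probabilities ``H 0.9 0.05 0.05 B 0.8 0.1 0.1``. Lines starting with
    ``#`` are ignored.
    """
    ss_rows: list = []
    sa_rows: list = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) == 2:
            ss_rows.append(tokens[0])
            sa_rows.append(tokens[1])
        elif len(tokens) == 8:
            ss_rows.append([float(t) for t in tokens[1:4]])
            sa_rows.append([float(t) for t in tokens[5:8]])
        else:
            raise FormatError(f"{path}:{lineno}: expected 2 or 8 fields")
    if not ss_rows:
        raise FormatError(f"profile file {path} has no residue rows")
    label_mode = isinstance(ss_rows[0], str)
    ss = ss_rows if label_mode else np.array(ss_rows)
    sa = sa_rows if label_mode else np.array(sa_rows)
    return encode_structure_profile(ss, sa)


def write_profile(profile: StructureProfile, path: str | Path) -> None:
    """Write a profile as label + probability lines (the 8-field layout)."""
    with open(path, "w") as fh:
        for ss_row, sa_row in zip(profile.ss, profile.sa):
            ss_lab = SS_CLASSES[int(np.argmax(ss_row))]
            sa_lab = SA_CLASSES[int(np.argmax(sa_row))]
            fh.write(
                f"{ss_lab} " + " ".join(f"{p:.6f}" for p in ss_row)
                + f" {sa_lab} " + " ".join(f"{p:.6f}" for p in sa_row) + "\n"
            )


def assemble_seq_tensor(pssm: PSSMProfile, profile: StructureProfile) -> SeqFeatureTensor:
    """Concatenate [PSSM | SS | SA] into the L x 26 sequence tensor."""
    if pssm.L != profile.L:
        raise ValueError(f"length mismatch: PSSM L={pssm.L}, profile L={profile.L}")
    return SeqFeatureTensor(np.hstack([pssm.scores, profile.ss, profile.sa]))
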