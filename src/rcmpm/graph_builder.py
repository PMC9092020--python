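"""Residue contact graph construction from a rough score matrix.

An edge joins residues i != j whose rough contact score reaches the edge
threshold (0.5 by default, suitable for probability-scaled maps). The
propagation operator of the graph network is the self-looped adjacency
A~ = A + I_L; optionally the edges carry the rough scores as weights, with
unit self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rcmpm.io_formats import ScoreMatrix


@dataclass
class ContactGraph:
    """Residue graph: binary adjacency A, self-looped A~, optional edge weights."""

    adjacency: np.ndarray
    weights: np.ndarray
    weighted: bool = False

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValueError("adjacency diagonal must be zero")

    @property
    def L(self) -> int:
        return self.adjacency.shape[0]

    @property
    def a_tilde(self) -> np.ndarray:
        """Self-looped adjacency A~ = A + I_L."""
        return self.adjacency + np.eye(self.L, dtype=self.adjacency.dtype)

    @property
    def propagation(self) -> np.ndarray:
        """Matrix used by graph convolution: weighted edges + unit self-loops,
        or the binary A~."""
        if self.weighted:
            return self.weights + np.eye(self.L)
        return self.a_tilde.astype(float)


def build_contact_graph(
    scores: ScoreMatrix, edge_threshold: float = 0.5, weighted: bool = False
) -> ContactGraph:
    """Threshold a rough score matrix into a contact graph.

    Edge (i, j) is present iff i != j and scores[i, j] >= edge_threshold.
    With ``weighted=True`` the edges keep their scores as weights (zero on
    non-edges); propagation then uses weights plus unit self-loops.
    """
    if not 0.0 <= edge_threshold <= 1.0:
        raise ValueError(f"edge_threshold must be in [0, 1], got {edge_threshold}")
    vals = scores.values
    A = (vals >= edge_threshold).astype(np.int8)
    np.fill_diagonal(A, 0)
    weights = np.where(A == 1, vals, 0.0)
    return ContactGraph(adjacency=A, weights=weights, weighted=weighted)
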