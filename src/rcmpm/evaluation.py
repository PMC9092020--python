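"""CASP-style contact evaluation: top-L/k precision by separation class.

For each separation class (short/medium/long) the unique i < j pairs are
ranked by predicted probability (ties broken by ascending (i, j)) and the
top floor(L/k) pairs, k in {10, 5, 2, 1}, are scored against the true map:
Accuracy = TP / (TP + FP). When fewer candidate pairs exist than floor(L/k),
all candidates are used and the denominator is the candidate count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from rcmpm.contact_geometry import ContactMap, separation_mask

TOP_K_LEVELS = (10, 5, 2, 1)
RANGE_NAMES = ("short", "medium", "long")


def _probs_of(pred) -> np.ndarray:
    probs = np.asarray(getattr(pred, "probs", pred), dtype=float)
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise ValueError(f"prediction must be a square map, got {probs.shape}")
    return probs


@dataclass
class EvalCell:
    precision: float
    tp: int
    fp: int
    n_selected: int
    no_candidates: bool = False


@dataclass
class EvalReport:
    """Precision per (separation range, top-L/k level)."""

    L: int
    cells: dict[tuple[str, int], EvalCell]

    def precision(self, range_name: str, k: int) -> float:
        return self.cells[(range_name, k)].precision

    def to_tsv(self) -> str:
        header = "range\t" + "\t".join(f"L/{k}" if k != 1 else "L" for k in TOP_K_LEVELS)
        lines = [header]
        for rng in RANGE_NAMES:
            vals = "\t".join(f"{self.cells[(rng, k)].precision:.3f}" for k in TOP_K_LEVELS)
            lines.append(f"{rng}\t{vals}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            rng: {str(k): self.cells[(rng, k)].precision for k in TOP_K_LEVELS}
            for rng in RANGE_NAMES
        }
        return json.dumps({"L": self.L, "precision": payload}, indent=2)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(self.to_json())
        else:
            path.write_text(self.to_tsv())


def rank_pairs(pred, range_name: str) -> list[tuple[int, int]]:
    """Unique i < j pairs of the named separation class, by descending
    probability then ascending (i, j)."""
    probs = _probs_of(pred)
    L = probs.shape[0]
    mask = np.triu(separation_mask(L, range_name))
    iu, ju = np.nonzero(mask)
    order = np.lexsort((ju, iu, -probs[iu, ju]))
    return [(int(iu[t]), int(ju[t])) for t in order]


def topk_accuracy(
    pred, truth: ContactMap, range_name: str, k: int,
    return_cell: bool = False,
):
    """Precision of the top floor(L/k) predicted pairs in a separation class."""
    if k not in TOP_K_LEVELS:
        raise ValueError(f"k must be one of {TOP_K_LEVELS}, got {k}")
    probs = _probs_of(pred)
    L = truth.L
    if probs.shape[0] != L:
        raise ValueError(f"prediction L={probs.shape[0]} but truth L={L}")
    ranked = rank_pairs(probs, range_name)
    m = L // k
    selected = ranked[:m]
    if not selected:
        cell = EvalCell(precision=0.0, tp=0, fp=0, n_selected=0, no_candidates=True)
        return cell if return_cell else 0.0
    tp = sum(int(truth.labels[i, j]) for i, j in selected)
    n_sel = len(selected)
    cell = EvalCell(
        precision=tp / n_sel, tp=tp, fp=n_sel - tp, n_selected=n_sel,
        no_candidates=False,
    )
    return cell if return_cell else cell.precision


def improvement_percent(refined: float, baseline: float) -> float:
    """Relative improvement 100 * (refined - baseline) / baseline, one decimal."""
    if baseline <= 0:
        raise ValueError("baseline precision must be positive")
    return round(100.0 * (refined - baseline) / baseline, 1)


def evaluate_report(pred, truth: ContactMap) -> EvalReport:
    """All 12 (range x k) precision cells for one protein."""
    probs = _probs_of(pred)
    cells = {
        (rng, k): topk_accuracy(probs, truth, rng, k, return_cell=True)
        for rng in RANGE_NAMES
        for k in TOP_K_LEVELS
    }
    return EvalReport(L=truth.L, cells=cells)


def mean_topk_accuracy(
    preds: list, truths: list[ContactMap], range_name: str, k: int
) -> float:
    """Dataset-level precision: unweighted mean of per-protein top-L/k cells."""
    if len(preds) != len(truths):
        raise ValueError("preds and truths length mismatch")
    vals = [topk_accuracy(p, t, range_name, k) for p, t in zip(preds, truths)]
    return float(np.mean(vals))
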