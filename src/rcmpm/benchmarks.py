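"""Reference long-range benchmark precisions for the refinement model.

Published top-L/k (k = 10, 5, 2, 1) long-range precisions of the refinement
network and the methods it is compared against, on the PDB25 test split and
the CASP10-12 target sets, plus the ablation without the graph-convolution
module. They let relative-improvement summaries (how much refining a rough
map gains over ranking it directly) be recomputed without access to the
underlying structure datasets.

``RCMPM (CCMpred)`` / ``RCMPM (RaptorX-Contact)`` denote the refinement
model run on the respective upstream rough contact map.
"""

from __future__ import annotations

from rcmpm.evaluation import improvement_percent

#: Number of protein targets behind each benchmark set.
DATASET_SIZES = {"PDB25": 500, "CASP10": 116, "CASP11": 102, "CASP12": 55}

#: Long-range precision at top L/10, L/5, L/2, L (in that order).
LONG_RANGE_PRECISION: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "PDB25": {
        "CCMpred": (0.528, 0.475, 0.361, 0.257),
        "R2C": (0.666, 0.667, 0.648, 0.449),
        "RaptorX-Contact": (0.774, 0.739, 0.633, 0.497),
        "RCMPM (CCMpred)": (0.718, 0.685, 0.582, 0.446),
        "RCMPM (RaptorX-Contact)": (0.784, 0.748, 0.646, 0.508),
        "RCMPM (without GCN)": (0.775, 0.741, 0.635, 0.498),
    },
    "CASP10": {
        "CCMpred": (0.533, 0.477, 0.355, 0.242),
        "R2C": (0.413, 0.306, 0.198, 0.143),
        "RaptorX-Contact": (0.674, 0.625, 0.490, 0.372),
        "RCMPM (CCMpred)": (0.639, 0.583, 0.455, 0.342),
        "RCMPM (RaptorX-Contact)": (0.673, 0.611, 0.495, 0.371),
    },
    "CASP11": {
        "CCMpred": (0.448, 0.393, 0.290, 0.206),
        "R2C": (0.500, 0.425, 0.307, 0.223),
        "RaptorX-Contact": (0.659, 0.608, 0.512, 0.396),
        "RCMPM (CCMpred)": (0.631, 0.593, 0.499, 0.385),
        "RCMPM (RaptorX-Contact)": (0.664, 0.619, 0.519, 0.402),
    },
    "CASP12": {
        "CCMpred": (0.447, 0.406, 0.296, 0.205),
        "R2C": (0.615, 0.601, 0.524, 0.407),
        "RaptorX-Contact": (0.583, 0.552, 0.438, 0.323),
        "RCMPM (CCMpred)": (0.558, 0.520, 0.403, 0.290),
        "RCMPM (RaptorX-Contact)": (0.608, 0.573, 0.445, 0.325),
    },
}

TOP_LEVEL_LABELS = ("L/10", "L/5", "L/2", "L")


def long_range_improvements(
    dataset: str, refined_method: str, baseline_method: str
) -> dict[str, float]:
    """Relative improvement (percent) of one method over another at each
    top-L/k level, recomputed from the reference precisions."""
    table = LONG_RANGE_PRECISION[dataset]
    refined = table[refined_method]
    baseline = table[baseline_method]
    return {
        label: improvement_percent(r, b)
        for label, r, b in zip(TOP_LEVEL_LABELS, refined, baseline)
    }
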