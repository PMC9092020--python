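"""The contact-map refinement network.

Architecture: a two-layer graph convolutional network over the self-looped
residue contact graph (propagation H <- ReLU(A~ . minmax(H) . W)), a 1D
residual network over the L x 26 sequence features, an outer concatenation
that lifts the two L x n embeddings to an L x L x 4n pairwise map joined
with the L x L x 5 pairwise features, and a 2D residual network ending in a
two-class softmax (contact / non-contact) per residue pair. Training
minimizes the cross-entropy averaged over all L^2 ordered pairs with plain
SGD (default learning rate 0.01).

Every residual block is two convolutions with ReLU activations applied to
the min-max-normalized block input, plus an identity skip; a width-1
convolution projects the skip path when the channel counts differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from rcmpm import nn
from rcmpm.contact_geometry import ContactMap
from rcmpm.graph_builder import ContactGraph
from rcmpm.pair_features import PairFeatureTensor
from rcmpm.seq_features import SeqFeatureTensor


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the refinement network.

    ``n`` is the embedding width shared by the GCN and 1D ResNet outputs.
    ``blocks_2d`` defaults to a desk-scale 4; the full-scale depth is 30.
    """

    n: int = 32
    gcn_layers: int = 2
    blocks_1d: int = 3
    blocks_2d: int = 4
    width_2d: int = 48
    kernel_1d: int = 5
    kernel_2d: int = 3
    learning_rate: float = 0.01
    epochs: int = 100
    seed: int = 0
    edge_threshold: float = 0.5
    weighted_graph: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.kernel_1d % 2 == 0 or self.kernel_2d % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.blocks_1d < 1 or self.blocks_2d < 0:
            raise ValueError("invalid block counts")

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Small configuration for CPU-scale experiments and tests."""
        base = cls(n=16, blocks_2d=4, width_2d=24)
        return replace(base, **overrides) if overrides else base

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ForwardTrace:
    """Intermediate activations of one forward pass (numpy arrays)."""

    x_gcn: np.ndarray  # (L, n)
    x_1dresnet: np.ndarray  # (L, n)
    x_1dfinal: np.ndarray  # (L, 2n)
    integrate_gcn: np.ndarray  # (L, L, 4n)
    x_2dinput: np.ndarray  # (L, L, 4n + 5)
    x_2dresnet: np.ndarray  # (L, L, width_2d)
    logits: np.ndarray  # (L, L, 2)


@dataclass
class Prediction:
    """Refined contact probabilities: symmetrized map plus per-pair class rows."""

    probs: np.ndarray  # (L, L) contact probability, symmetric
    class_probs: np.ndarray  # (L, L, 2) [non-contact, contact], rows sum to 1

    @property
    def L(self) -> int:
        return self.probs.shape[0]


@dataclass
class TrainResult:
    params: dict[str, nn.Tensor]
    config: ModelConfig
    loss_history: list[float] = field(default_factory=list)


def minmax_normalize(H: np.ndarray) -> np.ndarray:
    """Per-feature min-max map of a feature matrix to [0, 1] (constant columns -> 0)."""
    H = np.asarray(H, dtype=float)
    if not np.isfinite(H).all():
        raise ValueError("non-finite input to minmax_normalize")
    return nn.minmax_normalize_array(H)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def init_params(config: ModelConfig, rng: np.random.Generator | None = None) -> dict:
    """He-initialized weights; biases start at zero."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, k1, k2, w2 = config.n, config.kernel_1d, config.kernel_2d, config.width_2d
    params: dict[str, nn.Tensor] = {}
    params["gcn.w0"] = nn.parameter(_he(rng, (26, n), 26))
    params["gcn.w1"] = nn.parameter(_he(rng, (n, n), n))
    cin = 26
    for blk in range(config.blocks_1d):
        pre = f"res1d.{blk}"
        params[f"{pre}.conv1.w"] = nn.parameter(_he(rng, (k1, cin, n), k1 * cin))
        params[f"{pre}.conv1.b"] = nn.parameter(np.zeros(n))
        params[f"{pre}.conv2.w"] = nn.parameter(_he(rng, (k1, n, n), k1 * n))
        params[f"{pre}.conv2.b"] = nn.parameter(np.zeros(n))
        if cin != n:
            params[f"{pre}.skip.w"] = nn.parameter(_he(rng, (1, cin, n), cin))
        cin = n
    c2in = 4 * n + 5
    params["res2d.entry.w"] = nn.parameter(_he(rng, (1, 1, c2in, w2), c2in))
    params["res2d.entry.b"] = nn.parameter(np.zeros(w2))
    for blk in range(config.blocks_2d):
        pre = f"res2d.{blk}"
        params[f"{pre}.conv1.w"] = nn.parameter(_he(rng, (k2, k2, w2, w2), k2 * k2 * w2))
        params[f"{pre}.conv1.b"] = nn.parameter(np.zeros(w2))
        params[f"{pre}.conv2.w"] = nn.parameter(_he(rng, (k2, k2, w2, w2), k2 * k2 * w2))
        params[f"{pre}.conv2.b"] = nn.parameter(np.zeros(w2))
    params["res2d.head.w"] = nn.parameter(_he(rng, (1, 1, w2, 2), w2))
    params["res2d.head.b"] = nn.parameter(np.zeros(2))
    return params


def _as_array(x, attr: str) -> np.ndarray:
    return np.asarray(getattr(x, attr) if hasattr(x, attr) else x, dtype=float)


def _gcn(params: dict, prop: np.ndarray, x: nn.Tensor) -> nn.Tensor:
    a = nn.constant(prop)
    h = x
    for key in ("gcn.w0", "gcn.w1"):
        h = nn.relu(nn.matmul(nn.matmul(a, nn.minmax(h)), params[key]))
    return h


def _block1d(params: dict, prefix: str, x: nn.Tensor, n: int) -> nn.Tensor:
    z = nn.minmax(x)
    a = nn.relu(nn.conv1d(z, params[f"{prefix}.conv1.w"], params[f"{prefix}.conv1.b"]))
    a = nn.relu(nn.conv1d(a, params[f"{prefix}.conv2.w"], params[f"{prefix}.conv2.b"]))
    skip_key = f"{prefix}.skip.w"
    s = nn.conv1d(x, params[skip_key]) if skip_key in params else x
    return nn.add(a, s)


def _resnet1d(params: dict, config: ModelConfig, x: nn.Tensor) -> nn.Tensor:
    h = x
    for blk in range(config.blocks_1d):
        h = _block1d(params, f"res1d.{blk}", h, config.n)
    return h


def _block2d(params: dict, prefix: str, x: nn.Tensor) -> nn.Tensor:
    z = nn.minmax(x)
    a = nn.relu(nn.conv2d(z, params[f"{prefix}.conv1.w"], params[f"{prefix}.conv1.b"]))
    a = nn.relu(nn.conv2d(a, params[f"{prefix}.conv2.w"], params[f"{prefix}.conv2.b"]))
    return nn.add(a, x)


def _resnet2d(params: dict, config: ModelConfig, x2d: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
    h = nn.conv2d(x2d, params["res2d.entry.w"], params["res2d.entry.b"])
    for blk in range(config.blocks_2d):
        h = _block2d(params, f"res2d.{blk}", h)
    logits = nn.conv2d(h, params["res2d.head.w"], params["res2d.head.b"])
    return h, logits


def _outer_concat(x1dfinal: nn.Tensor, x_pair: nn.Tensor) -> nn.Tensor:
    L = x1dfinal.shape[0]
    row_i = nn.tile_rows(x1dfinal, L, axis=1)  # out[i, j] = rows of residue i
    row_j = nn.tile_rows(x1dfinal, L, axis=0)  # out[i, j] = rows of residue j
    return nn.concat_last([row_i, row_j, x_pair])


def _forward(
    params: dict, config: ModelConfig, prop: np.ndarray,
    x_seq: np.ndarray, x_pair: np.ndarray,
) -> dict[str, nn.Tensor]:
    xs = nn.constant(x_seq)
    xp = nn.constant(x_pair)
    x_gcn = _gcn(params, prop, xs)
    x_1d = _resnet1d(params, config, xs)
    x_1dfinal = nn.concat_last([x_1d, x_gcn])
    x_2dinput = _outer_concat(x_1dfinal, xp)
    x_2dres, logits = _resnet2d(params, config, x_2dinput)
    return {
        "x_gcn": x_gcn, "x_1dresnet": x_1d, "x_1dfinal": x_1dfinal,
        "x_2dinput": x_2dinput, "x_2dresnet": x_2dres, "logits": logits,
    }


# --- public forward operations (numpy in, numpy out) -----------------------


def gcn_forward(graph: ContactGraph, x_seq, params: dict) -> np.ndarray:
    """Two graph-convolution layers over the self-looped contact graph."""
    x = _as_array(x_seq, "features")
    if x.shape[0] != graph.L:
        raise ValueError(f"graph L={graph.L} but features have L={x.shape[0]}")
    return _gcn(params, graph.propagation, nn.constant(x)).data


def resnet1d_forward(x_seq, params: dict, config: ModelConfig) -> np.ndarray:
    """The 1D residual stack over the sequence features (length preserving)."""
    x = _as_array(x_seq, "features")
    return _resnet1d(params, config, nn.constant(x)).data


def outer_concat(x_gcn: np.ndarray, x_1d: np.ndarray, x_pair) -> np.ndarray:
    """Lift the two L x n embeddings into the L x L x (4n + 5) 2D input.

    Entry (i, j) carries [features of residue i, features of residue j,
    pairwise features of (i, j)], where the per-residue part is the
    concatenation [1D ResNet | GCN].
    """
    xg = np.asarray(x_gcn, dtype=float)
    x1 = np.asarray(x_1d, dtype=float)
    xp = _as_array(x_pair, "channels")
    if not (xg.shape[0] == x1.shape[0] == xp.shape[0]):
        raise ValueError("outer_concat length mismatch")
    x1dfinal = nn.constant(np.concatenate([x1, xg], axis=1))
    return _outer_concat(x1dfinal, nn.constant(xp)).data


def resnet2d_forward(x2d: np.ndarray, params: dict, config: ModelConfig) -> np.ndarray:
    """Entry projection, 2D residual stack, and the 2-class output head."""
    _, logits = _resnet2d(params, config, nn.constant(np.asarray(x2d, dtype=float)))
    return logits.data


def forward_trace(
    params: dict, config: ModelConfig, graph: ContactGraph, x_seq, x_pair
) -> ForwardTrace:
    """Full forward pass keeping every intermediate activation."""
    xs = _as_array(x_seq, "features")
    xp = _as_array(x_pair, "channels")
    acts = _forward(params, config, graph.propagation, xs, xp)
    n = config.n
    return ForwardTrace(
        x_gcn=acts["x_gcn"].data,
        x_1dresnet=acts["x_1dresnet"].data,
        x_1dfinal=acts["x_1dfinal"].data,
        integrate_gcn=acts["x_2dinput"].data[:, :, : 4 * n],
        x_2dinput=acts["x_2dinput"].data,
        x_2dresnet=acts["x_2dresnet"].data,
        logits=acts["logits"].data,
    )


def predict(
    params: dict, config: ModelConfig, graph: ContactGraph, x_seq, x_pair
) -> Prediction:
    """Refined contact map: softmax over the two class channels, then
    symmetrization (y + y^T) / 2."""
    xs = _as_array(x_seq, "features")
    xp = _as_array(x_pair, "channels")
    logits = _forward(params, config, graph.propagation, xs, xp)["logits"].data
    class_probs = nn.softmax_array(logits)
    probs = (class_probs[:, :, 1] + class_probs[:, :, 1].T) / 2.0
    return Prediction(probs=probs, class_probs=class_probs)


def _one_hot_truth(truth: ContactMap) -> np.ndarray:
    t = truth.labels.astype(float)
    return np.stack([1.0 - t, t], axis=-1)


def loss(pred, truth: ContactMap) -> float:
    """Two-class cross-entropy averaged over all L^2 ordered pairs.

    ``pred`` may be a Prediction or an (L, L, 2) array of class
    probabilities. Probabilities are clamped at 1e-12 inside the log.
    """
    class_probs = pred.class_probs if isinstance(pred, Prediction) else np.asarray(pred)
    targets = _one_hot_truth(truth)
    if class_probs.shape != targets.shape:
        raise ValueError(
            f"prediction shape {class_probs.shape} != truth shape {targets.shape}"
        )
    L = truth.L
    return -float(
        (targets * np.log(np.clip(class_probs, 1e-12, None))).sum()
    ) / (L * L)


@dataclass
class TrainExample:
    """One protein: features, contact graph, and (for training) the true map."""

    x_seq: np.ndarray
    x_pair: np.ndarray
    graph: ContactGraph
    truth: ContactMap | None = None

    def __post_init__(self) -> None:
        self.x_seq = _as_array(self.x_seq, "features")
        self.x_pair = _as_array(self.x_pair, "channels")


def train(
    dataset: list[TrainExample], config: ModelConfig,
    params: dict | None = None,
) -> TrainResult:
    """SGD over proteins (one protein per step, variable L), seeded and
    reproducible. Raises TrainingDiverged on a non-finite loss."""
    if not dataset:
        raise ValueError("empty training dataset")
    if any(ex.truth is None for ex in dataset):
        raise ValueError("every training example needs a ground-truth contact map")
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_params(config, rng)
    opt = nn.SGD(list(params.values()), lr=config.learning_rate)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        epoch_losses = []
        for idx in order:
            ex = dataset[idx]
            acts = _forward(params, config, ex.graph.propagation, ex.x_seq, ex.x_pair)
            obj = nn.softmax_cross_entropy(acts["logits"], _one_hot_truth(ex.truth))
            if not np.isfinite(obj.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, protein {idx}"
                )
            opt.zero_grad()
            obj.backward()
            opt.step()
            epoch_losses.append(float(obj.data))
        history.append(float(np.mean(epoch_losses)))
    return TrainResult(params=params, config=config, loss_history=history)


CHECKPOINT_VERSION = 1


def save_checkpoint(result: TrainResult | dict, config: ModelConfig, path: str | Path) -> None:
    params = result.params if isinstance(result, TrainResult) else result
    header = json.dumps({"version": CHECKPOINT_VERSION, "config": config.to_dict()})
    arrays = {k.replace(".", "__"): v.data for k, v in params.items()}
    np.savez(path, __header__=np.array(header), **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict, ModelConfig]:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__header__"]))
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {header.get('version')}")
        config = ModelConfig(**header["config"])
        params = {
            k.replace("__", "."): nn.parameter(data[k])
            for k in data.files
            if k != "__header__"
        }
    return params, config
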