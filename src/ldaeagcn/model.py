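"""Edge-attention graph convolutional classifier for pair graphs.

One graph convolution layer runs four parallel blocks, one per edge
category (core / known-association / lncRNA-similarity / disease-similarity).
A block turns its (N+M, N+M, 2) edge tensor into an attention adjacency: the
logit of an existing edge is an affine map ``a * weight + b`` of the
continuous channel-1 weight, normalised by a row-wise softmax over existing
edges (rows without edges stay all-zero).  An identity self-edge is added to
the normalised adjacency so isolated nodes retain their features.  The block
output is ``ReLU((A + I) H W)``; the four block outputs concatenate along
the feature axis.  After the configured number of layers the node embeddings
are flattened in fixed node order (query nodes first — positions are
semantically fixed in these graphs) and passed through three fully connected
layers with ReLU and dropout between, ending in a sigmoid association score.

The network is small and fixed-shape, so it is implemented directly in
numpy with analytic gradients (verified against finite differences in the
test suite).  Training is mini-batch SGD with momentum on binary
cross-entropy; the final linear layer is zero-initialised so an untrained
model scores exactly 0.5 and starts from loss -ln(0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cnwgsn import EDGE_CATEGORIES, PairGraph

DEFAULT_DROPOUT = 0.3
DEFAULT_LR = 0.01


@dataclass
class ModelConfig:
    n_gc_layers: int = 4
    gc_block_dim: int = 4          # per-edge-category width; layer output is 4x this
    fc_dims: tuple[int, int] = (32, 16)
    n_fc_layers: int = 3
    dropout_rate: float = DEFAULT_DROPOUT
    learning_rate: float = DEFAULT_LR
    momentum: float = 0.9
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gc_layers < 1 or self.gc_block_dim < 1:
            raise ValueError("layer counts and widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if len(self.fc_dims) != self.n_fc_layers - 1:
            raise ValueError("fc_dims must list the widths of all but the output layer")


@dataclass
class ModelParams:
    """gc[layer][category] = {'W': matrix, 'a': scalar, 'b': scalar}; fc = [[W, b], ...]."""

    gc: list[dict[str, dict[str, np.ndarray | float]]]
    fc: list[list[np.ndarray]]
    n_nodes: int
    n_features: int


def init_params(config: ModelConfig, n_nodes: int, n_features: int) -> ModelParams:
    """Seeded fan-in-scaled uniform init; attention maps start at identity (a=1, b=0);
    the final linear layer is zero-initialised."""
    rng = np.random.default_rng(config.seed)
    gc = []
    din = n_features
    for _ in range(config.n_gc_layers):
        layer = {}
        for cat in EDGE_CATEGORIES:
            bound = 1.0 / np.sqrt(din)
            layer[cat] = {
                "W": rng.uniform(-bound, bound, size=(din, config.gc_block_dim)),
                "a": 1.0,
                "b": 0.0,
            }
        gc.append(layer)
        din = config.gc_block_dim * len(EDGE_CATEGORIES)
    fc = []
    widths = [n_nodes * din, *config.fc_dims, 1]
    for k in range(len(widths) - 1):
        if k == len(widths) - 2:
            w = np.zeros((widths[k], widths[k + 1]))
        else:
            bound = 1.0 / np.sqrt(widths[k])
            w = rng.uniform(-bound, bound, size=(widths[k], widths[k + 1]))
        fc.append([w, np.zeros(widths[k + 1])])
    return ModelParams(gc, fc, n_nodes, n_features)


# ---------------------------------------------------------------------------
# forward / backward


def attention_adjacency(edge_tensor: np.ndarray, a: float, b: float) -> np.ndarray:
    """Row-softmax attention over the existing edges of one (n, n, 2) tensor."""
    A, _ = _attention_batch(np.asarray(edge_tensor, float)[None], a, b)
    return A[0]


def _attention_batch(E: np.ndarray, a: float, b: float):
    mask = E[..., 0] > 0.0
    w = E[..., 1]
    logits = np.where(mask, a * w + b, -np.inf)
    row_max = logits.max(axis=-1, keepdims=True)
    has_edge = np.isfinite(row_max)
    shifted = np.where(mask, logits - np.where(has_edge, row_max, 0.0), -np.inf)
    expv = np.where(mask, np.exp(shifted), 0.0)
    denom = expv.sum(axis=-1, keepdims=True)
    A = np.where(denom > 0.0, expv / np.where(denom > 0.0, denom, 1.0), 0.0)
    return A, (mask, w, A)


def _attention_backward(dA: np.ndarray, cache):
    mask, w, A = cache
    s = (A * dA).sum(axis=-1, keepdims=True)
    dlogits = A * (dA - s)
    da = float((dlogits * w)[mask].sum())
    db = float(dlogits[mask].sum())
    return da, db


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def pack_graphs(graphs: list[PairGraph]) -> dict:
    """Stack same-shape pair graphs into batched arrays for the network."""
    if not graphs:
        raise ValueError("no graphs to pack")
    edges = {cat: np.stack([g.edge_tensor(cat) for g in graphs]) for cat in EDGE_CATEGORIES}
    feats = np.stack([np.asarray(g.node_features, float) for g in graphs])
    labels = (
        np.array([g.label for g in graphs], float)
        if all(g.label is not None for g in graphs)
        else None
    )
    return {"edges": edges, "H0": feats, "labels": labels}


def _forward_batch(batch: dict, params: ModelParams, config: ModelConfig,
                   train_mode: bool = False, rng: np.random.Generator | None = None):
    H = batch["H0"]
    B, n, _ = H.shape
    eye = np.eye(n)
    gc_caches = []
    for layer in params.gc:
        outs, layer_cache = [], []
        for cat in EDGE_CATEGORIES:
            p = layer[cat]
            A, att_cache = _attention_batch(batch["edges"][cat], p["a"], p["b"])
            M = A + eye
            X = H @ p["W"]
            Z = M @ X
            Hc = np.maximum(Z, 0.0)
            outs.append(Hc)
            layer_cache.append((att_cache, M, X, Z, H))
        gc_caches.append(layer_cache)
        H = np.concatenate(outs, axis=-1)

    x = H.reshape(B, -1)
    fc_caches = []
    h = x
    keep = 1.0 - config.dropout_rate
    for k, (W, b) in enumerate(params.fc):
        z = h @ W + b
        if k < len(params.fc) - 1:
            act = np.maximum(z, 0.0)
            if train_mode and config.dropout_rate > 0.0:
                if rng is None:
                    raise ValueError("train_mode dropout requires an rng")
                drop = (rng.random(act.shape) < keep) / keep
                out = act * drop
            else:
                drop = None
                out = act
            fc_caches.append((h, z, drop))
            h = out
        else:
            fc_caches.append((h, z, None))
            logit = z[:, 0]
    if not np.isfinite(logit).all():
        raise FloatingPointError("NaN or Inf in network activations")
    scores = _sigmoid(logit)
    return scores, {"gc": gc_caches, "fc": fc_caches, "B": B}


def _backward_batch(dlogit: np.ndarray, batch: dict, params: ModelParams,
                    config: ModelConfig, cache: dict) -> dict:
    B = cache["B"]
    grads = {
        "gc": [
            {cat: {"W": np.zeros_like(layer[cat]["W"]), "a": 0.0, "b": 0.0}
             for cat in EDGE_CATEGORIES}
            for layer in params.gc
        ],
        "fc": [[np.zeros_like(W), np.zeros_like(b)] for W, b in params.fc],
    }
    dh = dlogit[:, None]
    for k in range(len(params.fc) - 1, -1, -1):
        W, _ = params.fc[k]
        h_in, z, drop = cache["fc"][k]
        if k < len(params.fc) - 1:
            if drop is not None:
                dh = dh * drop
            dh = dh * (z > 0.0)
        grads["fc"][k][0] = h_in.T @ dh
        grads["fc"][k][1] = dh.sum(axis=0)
        dh = dh @ W.T

    n = params.n_nodes
    dH = dh.reshape(B, n, -1)
    for li in range(len(params.gc) - 1, -1, -1):
        layer = params.gc[li]
        width = layer[EDGE_CATEGORIES[0]]["W"].shape[1]
        dH_in = None
        for ci, cat in enumerate(EDGE_CATEGORIES):
            att_cache, M, X, Z, H_in = cache["gc"][li][ci]
            dHc = dH[..., ci * width:(ci + 1) * width]
            dZ = dHc * (Z > 0.0)
            dM = dZ @ X.transpose(0, 2, 1)
            dX = M.transpose(0, 2, 1) @ dZ
            grads["gc"][li][cat]["W"] = np.einsum("bni,bnj->ij", H_in, dX)
            da, db = _attention_backward(dM, att_cache)
            grads["gc"][li][cat]["a"] = da
            grads["gc"][li][cat]["b"] = db
            contrib = dX @ layer[cat]["W"].T
            dH_in = contrib if dH_in is None else dH_in + contrib
        dH = dH_in
    return grads


def bce_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(scores, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# public API


def model_forward(graph: PairGraph, params: ModelParams, config: ModelConfig,
                  train_mode: bool = False,
                  rng: np.random.Generator | None = None) -> float:
    """Association score in [0, 1] for a single pair graph."""
    batch = pack_graphs([graph])
    scores, _ = _forward_batch(batch, params, config, train_mode, rng)
    return float(scores[0])


def gc_layer_forward(H: np.ndarray, graph: PairGraph, layer_params: dict) -> np.ndarray:
    """One graph-convolution layer on a single graph (block outputs concatenated)."""
    n = graph.n_nodes
    eye = np.eye(n)
    outs = []
    for cat in EDGE_CATEGORIES:
        p = layer_params[cat]
        A = attention_adjacency(graph.edge_tensor(cat), p["a"], p["b"])
        outs.append(np.maximum((A + eye) @ (H @ p["W"]), 0.0))
    return np.concatenate(outs, axis=-1)


def predict_scores(params: ModelParams, graphs: list[PairGraph],
                   config: ModelConfig) -> list[float]:
    """Deterministic scores (dropout off), order-aligned with the input."""
    if not graphs:
        return []
    batch = pack_graphs(graphs)
    scores, _ = _forward_batch(batch, params, config, train_mode=False)
    return [float(s) for s in scores]


def train_model(graphs: list[PairGraph], config: ModelConfig) -> tuple[ModelParams, list[float]]:
    """Mini-batch SGD-with-momentum training on binary cross-entropy.

    Fully seeded: initialisation, shuffling and dropout all derive from
    ``config.seed``, so repeat runs are bitwise identical single-threaded.
    """
    labels = np.array([g.label for g in graphs], float)
    if any(g.label is None for g in graphs):
        raise ValueError("all training graphs need labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires graphs of both classes")
    batch = pack_graphs(graphs)
    n_nodes, n_features = batch["H0"].shape[1:]
    params = init_params(config, n_nodes, n_features)
    rng = np.random.default_rng(config.seed + 1)

    velocity = _map_params(params, lambda v: np.zeros_like(np.asarray(v, float)))
    B_total = len(graphs)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(B_total)
        epoch_loss = 0.0
        for start in range(0, B_total, config.batch_size):
            idx = order[start:start + config.batch_size]
            sub = {
                "edges": {c: batch["edges"][c][idx] for c in EDGE_CATEGORIES},
                "H0": batch["H0"][idx],
            }
            y = labels[idx]
            scores, cache = _forward_batch(sub, params, config, train_mode=True, rng=rng)
            epoch_loss += bce_loss(scores, y) * len(idx)
            dlogit = (scores - y) / len(idx)
            grads = _backward_batch(dlogit, sub, params, config, cache)
            _sgd_update(params, grads, velocity, config)
        loss = epoch_loss / B_total
        if not np.isfinite(loss):
            raise FloatingPointError("training loss became non-finite")
        history.append(loss)
    return params, history


def _map_params(params: ModelParams, fn):
    return {
        "gc": [
            {cat: {k: fn(layer[cat][k]) for k in ("W", "a", "b")} for cat in EDGE_CATEGORIES}
            for layer in params.gc
        ],
        "fc": [[fn(W), fn(b)] for W, b in params.fc],
    }


def _sgd_update(params: ModelParams, grads: dict, velocity: dict, config: ModelConfig) -> None:
    mu, lr = config.momentum, config.learning_rate
    for li, layer in enumerate(params.gc):
        for cat in EDGE_CATEGORIES:
            for k in ("W", "a", "b"):
                v = mu * velocity["gc"][li][cat][k] - lr * grads["gc"][li][cat][k]
                velocity["gc"][li][cat][k] = v
                layer[cat][k] = layer[cat][k] + v
    for k, (W, b) in enumerate(params.fc):
        vW = mu * velocity["fc"][k][0] - lr * grads["fc"][k][0]
        vb = mu * velocity["fc"][k][1] - lr * grads["fc"][k][1]
        velocity["fc"][k][0], velocity["fc"][k][1] = vW, vb
        params.fc[k][0] = W + vW
        params.fc[k][1] = b + vb


# ---------------------------------------------------------------------------
# parameter (de)serialisation and flat views (used by the gradient checks)


def get_flat_params(params: ModelParams) -> np.ndarray:
    parts = []
    for layer in params.gc:
        for cat in EDGE_CATEGORIES:
            parts.append(np.asarray(layer[cat]["W"], float).ravel())
            parts.append(np.array([layer[cat]["a"], layer[cat]["b"]], float))
    for W, b in params.fc:
        parts.append(W.ravel())
        parts.append(b.ravel())
    return np.concatenate(parts)


def set_flat_params(params: ModelParams, vec: np.ndarray) -> None:
    pos = 0

    def take(shape):
        nonlocal pos
        size = int(np.prod(shape))
        out = vec[pos:pos + size].reshape(shape)
        pos += size
        return out

    for layer in params.gc:
        for cat in EDGE_CATEGORIES:
            layer[cat]["W"] = take(layer[cat]["W"].shape).copy()
            ab = take((2,))
            layer[cat]["a"], layer[cat]["b"] = float(ab[0]), float(ab[1])
    for k, (W, b) in enumerate(params.fc):
        params.fc[k][0] = take(W.shape).copy()
        params.fc[k][1] = take(b.shape).copy()
    if pos != vec.size:
        raise ValueError("flat parameter vector has the wrong length")


def flat_gradients(grads: dict, params: ModelParams) -> np.ndarray:
    parts = []
    for li in range(len(params.gc)):
        for cat in EDGE_CATEGORIES:
            parts.append(np.asarray(grads["gc"][li][cat]["W"], float).ravel())
            parts.append(np.array([grads["gc"][li][cat]["a"], grads["gc"][li][cat]["b"]], float))
    for gW, gb in grads["fc"]:
        parts.append(gW.ravel())
        parts.append(gb.ravel())
    return np.concatenate(parts)


def loss_and_gradients(graphs: list[PairGraph], params: ModelParams,
                       config: ModelConfig) -> tuple[float, dict]:
    """Full-batch BCE loss and analytic parameter gradients (dropout off)."""
    batch = pack_graphs(graphs)
    labels = np.array([g.label for g in graphs], float)
    scores, cache = _forward_batch(batch, params, config, train_mode=False)
    loss = bce_loss(scores, labels)
    dlogit = (scores - labels) / len(graphs)
    grads = _backward_batch(dlogit, batch, params, config, cache)
    return loss, grads


def save_params(params: ModelParams, config: ModelConfig, path: str | Path) -> None:
    """Checkpoint: npz of parameter arrays plus a JSON config echo."""
    arrays = {"__meta__": np.frombuffer(
        json.dumps({
            "n_nodes": params.n_nodes, "n_features": params.n_features,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(config).items()},
        }).encode(), dtype=np.uint8)}
    for li, layer in enumerate(params.gc):
        for cat in EDGE_CATEGORIES:
            arrays[f"gc{li}_{cat}_W"] = layer[cat]["W"]
            arrays[f"gc{li}_{cat}_ab"] = np.array([layer[cat]["a"], layer[cat]["b"]])
    for k, (W, b) in enumerate(params.fc):
        arrays[f"fc{k}_W"] = W
        arrays[f"fc{k}_b"] = b
    np.savez(path, **arrays)


def load_params(path: str | Path) -> tuple[ModelParams, ModelConfig]:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_dict = meta["config"]
    cfg_dict["fc_dims"] = tuple(cfg_dict["fc_dims"])
    config = ModelConfig(**cfg_dict)
    gc = []
    for li in range(config.n_gc_layers):
        layer = {}
        for cat in EDGE_CATEGORIES:
            ab = data[f"gc{li}_{cat}_ab"]
            layer[cat] = {"W": data[f"gc{li}_{cat}_W"], "a": float(ab[0]), "b": float(ab[1])}
        gc.append(layer)
    fc = []
    for k in range(config.n_fc_layers):
        fc.append([data[f"fc{k}_W"], data[f"fc{k}_b"]])
    params = ModelParams(gc, fc, meta["n_nodes"], meta["n_features"])
    return params, config
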