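"""Edge-aware graph-attention classifier of DSB bins (DSB-GNN).

The model stacks graph-attention layers in which the attention coefficient of
a neighbor incorporates the encoded contact count of the connecting edge:

    alpha_ij = softmax_j( LeakyReLU( beta^T [ W_N h_i || W_N h_j || W_E h_(i,j) ] ) )
    h_i'     = sigma( sum_j alpha_ij W h_j )

Input node features (1346-long k-mer/CTCF/DNase vectors) are augmented with a
sinusoidal positional encoding of the bin index and a learnable centrality
(degree) embedding.  Per-layer outputs are combined by jumping-knowledge
concatenation, joined with the mean encoded feature of the node's incident
edges, and mapped through a logistic readout to a per-bin DSB probability.

Evaluation follows a leave-one-chromosome-out protocol: one chromosome held
out for testing, one for validation, the rest for training.  Trained with
full-batch Adam on the cross-entropy loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from ._autodiff import Adam, Tensor, concat, segment_softmax, segment_sum
from .genome_io import ContactGraph, kmer_feature_length

__all__ = [
    "ModelConfig",
    "GraphTensors",
    "DSBGNN",
    "positional_encoding",
    "attention_coefficients",
    "loco_split",
    "train",
    "evaluate",
]


@dataclass
class ModelConfig:
    """Hyperparameters and ablation switches of the DSB classifier."""

    hidden_dim: int = 32
    n_layers: int = 3
    n_heads: int = 2
    learning_rate: float = 5e-3
    epochs: int = 400
    dropout: float = 0.1
    weight_decay: float = 1e-3
    feature_noise: float = 0.5  # std of Gaussian input augmentation during training
    edge_transform: str = "linear"  # contact-count transform: "linear" or "log1p"
    edge_scale: float = 0.1  # multiplier for the "linear" transform
    class_weighting: bool = False
    seed: int = 0
    leaky_slope: float = 0.2
    degree_cap: int = 64
    nonlinearity: str = "relu"  # sigma in the update rule
    # ablation switches
    use_kmer: bool = True
    use_ctcf: bool = True
    use_dnase: bool = True
    zero_adjacency: bool = False
    use_jk: bool = True
    use_positional: bool = True
    use_centrality: bool = True
    use_edge_encoding: bool = True

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")


def positional_encoding(positions, dim: int) -> np.ndarray:
    """Sinusoidal (Transformer-style) encoding of genome-bin indices.

    Even components sin(pos / 10000^(2i/d)), odd components cos of the same
    angle; every entry lies in [-1, 1].
    """
    if dim % 2 != 0:
        raise ValueError("encoding dimension must be even")
    pos = np.atleast_1d(np.asarray(positions, dtype=np.float64))
    if (pos < 0).any():
        raise ValueError("positions must be non-negative")
    i = np.arange(dim // 2)
    angles = pos[:, None] / (10000.0 ** (2 * i / dim))[None, :]
    out = np.empty((len(pos), dim))
    out[:, 0::2] = np.sin(angles)
    out[:, 1::2] = np.cos(angles)
    return out if np.ndim(positions) else out[0]


def attention_coefficients(
    h_i: np.ndarray,
    neighbors: Sequence[np.ndarray],
    edge_feats: Sequence[np.ndarray],
    beta: np.ndarray,
    w_n: np.ndarray,
    w_e: np.ndarray,
    slope: float = 0.2,
) -> np.ndarray:
    """Edge-aware attention coefficients of one node over its neighbors.

    Direct transcription of the attention rule; returns the softmax-normalized
    alpha_ij in the order of `neighbors`.  Empty neighborhood -> empty array.
    """
    if len(neighbors) == 0:
        return np.zeros(0)
    scores = []
    for h_j, h_e in zip(neighbors, edge_feats):
        z = np.concatenate([w_n @ h_i, w_n @ h_j, w_e @ h_e])
        s = float(beta @ z)
        scores.append(s if s > 0 else slope * s)
    scores = np.asarray(scores)
    e = np.exp(scores - scores.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# graph tensors
# ---------------------------------------------------------------------------

@dataclass
class GraphTensors:
    """Array view of a contact (sub)graph consumed by the model.

    ``pos`` and ``deg`` are the bin indices and degrees *in the source
    graph*, so that predictions on an induced subgraph match the full graph
    wherever locality allows.
    """

    n: int
    X: np.ndarray  # (n, n_features)
    pos: np.ndarray  # (n,) original bin indices
    deg: np.ndarray  # (n,) original degrees
    labels: Optional[np.ndarray]
    ue_pairs: List[Tuple[int, int]]  # local node pairs, i < j
    ue_count: np.ndarray  # (n_ue,) raw contact counts
    dir_src: np.ndarray  # (2 * n_ue,)
    dir_dst: np.ndarray
    dir_ue: np.ndarray  # undirected edge id per directed edge
    node_ids: np.ndarray  # original node ids (identity for a full graph)

    @classmethod
    def from_graph(cls, graph: ContactGraph) -> "GraphTensors":
        n = graph.n_nodes
        pairs = sorted(graph.edges)
        counts = np.array([graph.edges[p] for p in pairs], dtype=np.float64)
        return cls.from_arrays(
            X=graph.features if graph.features is not None else np.zeros((n, kmer_feature_length() + 2)),
            pos=np.arange(n),
            deg=graph.degrees(),
            labels=graph.labels,
            ue_pairs=pairs,
            ue_count=counts,
            node_ids=np.arange(n),
        )

    @classmethod
    def from_arrays(cls, X, pos, deg, labels, ue_pairs, ue_count, node_ids) -> "GraphTensors":
        n = X.shape[0]
        if ue_pairs:
            src = np.array([p[0] for p in ue_pairs] + [p[1] for p in ue_pairs])
            dst = np.array([p[1] for p in ue_pairs] + [p[0] for p in ue_pairs])
            ue = np.concatenate([np.arange(len(ue_pairs))] * 2)
        else:
            src = dst = ue = np.zeros(0, dtype=np.int64)
        return cls(
            n=n,
            X=np.asarray(X, dtype=np.float64),
            pos=np.asarray(pos),
            deg=np.asarray(deg),
            labels=None if labels is None else np.asarray(labels),
            ue_pairs=list(ue_pairs),
            ue_count=np.asarray(ue_count, dtype=np.float64),
            dir_src=src,
            dir_dst=dst,
            dir_ue=ue,
            node_ids=np.asarray(node_ids),
        )

    def without_edge(self, ue_index: int) -> "GraphTensors":
        """Copy with one undirected edge removed and endpoint degrees decremented."""
        i, j = self.ue_pairs[ue_index]
        pairs = [p for k, p in enumerate(self.ue_pairs) if k != ue_index]
        counts = np.delete(self.ue_count, ue_index)
        deg = self.deg.copy()
        deg[i] -= 1
        deg[j] -= 1
        return GraphTensors.from_arrays(
            self.X, self.pos, deg, self.labels, pairs, counts, self.node_ids
        )


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class DSBGNN:
    """Edge-aware multi-head GAT with JK readout, on a numpy autodiff tape."""

    def __init__(self, config: ModelConfig, n_features: int = kmer_feature_length() + 2):
        self.config = config
        self.n_features = n_features
        self.loss_history: List[float] = []
        rng = np.random.default_rng(config.seed)
        self.params: Dict[str, Tensor] = {}
        d = config.hidden_dim

        def glorot(name, shape):
            scale = np.sqrt(6.0 / (shape[0] + shape[-1])) if len(shape) > 1 else 0.1
            self.params[name] = Tensor(rng.uniform(-scale, scale, shape), requires_grad=True)

        def zeros(name, shape):
            self.params[name] = Tensor(np.zeros(shape), requires_grad=True)

        glorot("W_in", (n_features, d))
        zeros("b_in", (d,))
        glorot("cent_emb", (config.degree_cap + 1, d))
        glorot("W_edge", (1, d))
        zeros("b_edge", (d,))
        for l in range(config.n_layers):
            d_out = d if l == config.n_layers - 1 else d // config.n_heads
            for h in range(config.n_heads):
                glorot(f"W_N_{l}_{h}", (d, d_out))
                glorot(f"W_E_{l}_{h}", (d, d_out))
                glorot(f"W_{l}_{h}", (d, d_out))
                glorot(f"beta_i_{l}_{h}", (d_out,))
                glorot(f"beta_j_{l}_{h}", (d_out,))
                glorot(f"beta_e_{l}_{h}", (d_out,))
                zeros(f"b_{l}_{h}", (d_out,))
        jk_dim = d * config.n_layers if config.use_jk else d
        glorot("W_out", (jk_dim + d, 1))
        zeros("b_out", (1,))

    # -- feature ablation --------------------------------------------------
    def _ablate(self, X: np.ndarray) -> np.ndarray:
        cfg = self.config
        if cfg.use_kmer and cfg.use_ctcf and cfg.use_dnase:
            return X
        X = X.copy()
        nk = X.shape[1] - 2
        if not cfg.use_kmer:
            X[:, :nk] = 0.0
        if not cfg.use_ctcf:
            X[:, nk] = 0.0
        if not cfg.use_dnase:
            X[:, nk + 1] = 0.0
        return X

    def _nonlin(self, t: Tensor) -> Tensor:
        if self.config.nonlinearity == "relu":
            return t.relu()
        if self.config.nonlinearity == "leaky_relu":
            return t.leaky_relu(self.config.leaky_slope)
        if self.config.nonlinearity == "sigmoid":
            return t.sigmoid()
        raise ValueError(f"unknown nonlinearity {self.config.nonlinearity!r}")

    def encode_nodes(self, gt: GraphTensors, feat_mask: Optional[Tensor] = None):
        """Node-feature encoding + positional term (degree term added later)."""
        Xt = Tensor(self._ablate(gt.X))
        if feat_mask is not None:
            Xt = Xt * feat_mask.sigmoid()
        x = Xt @ self.params["W_in"] + self.params["b_in"]
        if self.config.use_positional:
            x = x + Tensor(positional_encoding(gt.pos, self.config.hidden_dim))
        return x

    def encode_edges(self, gt: GraphTensors):
        """Edge encoding: scalar contact intensity -> hidden-dim edge feature."""
        if self.config.edge_transform == "log1p":
            c = np.log1p(gt.ue_count)
        elif self.config.edge_transform == "linear":
            c = gt.ue_count * self.config.edge_scale
        else:
            raise ValueError(f"unknown edge_transform {self.config.edge_transform!r}")
        if self.config.zero_adjacency or not self.config.use_edge_encoding:
            c = np.zeros_like(c)
        return Tensor(c[:, None]) @ self.params["W_edge"] + self.params["b_edge"]

    def forward(
        self,
        gt: GraphTensors,
        edge_mask: Optional[Tensor] = None,
        feat_mask: Optional[Tensor] = None,
        x_base=None,
        he_base=None,
        dropout_rng: Optional[np.random.Generator] = None,
        collect_states: Optional[list] = None,
    ) -> Tensor:
        """Per-node DSB logits.  ``edge_mask`` holds raw (pre-sigmoid) values
        per undirected edge; its sigmoid scales messages and readout terms.

        ``x_base`` / ``he_base`` allow reuse of the (expensive) input
        encodings across repeated structural perturbations of one graph.
        """
        cfg = self.config
        n = gt.n
        if x_base is None:
            x = self.encode_nodes(gt, feat_mask)
        else:
            x = x_base if isinstance(x_base, Tensor) else Tensor(x_base)
        if cfg.use_centrality:
            capped = np.minimum(gt.deg, cfg.degree_cap)
            x = x + self.params["cent_emb"].gather(capped)
        if he_base is None:
            he = self.encode_edges(gt)
        else:
            he = he_base if isinstance(he_base, Tensor) else Tensor(he_base)

        has_edges = len(gt.ue_pairs) > 0
        mask_dir = None
        if edge_mask is not None and has_edges:
            mask_dir = edge_mask.sigmoid().gather(gt.dir_ue)

        h = x
        layer_outs = []
        for l in range(cfg.n_layers):
            last = l == cfg.n_layers - 1
            head_outs = []
            for k in range(cfg.n_heads):
                if has_edges:
                    hn = h @ self.params[f"W_N_{l}_{k}"]
                    hev = he @ self.params[f"W_E_{l}_{k}"]
                    scores = (
                        (hn.gather(gt.dir_src) * self.params[f"beta_i_{l}_{k}"]).sum(axis=1)
                        + (hn.gather(gt.dir_dst) * self.params[f"beta_j_{l}_{k}"]).sum(axis=1)
                        + (hev.gather(gt.dir_ue) * self.params[f"beta_e_{l}_{k}"]).sum(axis=1)
                    ).leaky_relu(cfg.leaky_slope)
                    alpha = segment_softmax(scores, gt.dir_src, n)
                    weights = alpha * mask_dir if mask_dir is not None else alpha
                    msg_src = (h @ self.params[f"W_{l}_{k}"]).gather(gt.dir_dst)
                    msg = segment_sum(weights.reshape(-1, 1) * msg_src, gt.dir_src, n)
                else:
                    msg = Tensor(np.zeros((n, self.params[f"W_{l}_{k}"].shape[1])))
                head_outs.append(self._nonlin(msg + self.params[f"b_{l}_{k}"]))
            if last:
                acc = head_outs[0]
                for extra in head_outs[1:]:
                    acc = acc + extra
                h = acc * (1.0 / cfg.n_heads)
            else:
                h = concat(head_outs, axis=1) if cfg.n_heads > 1 else head_outs[0]
            if dropout_rng is not None and cfg.dropout > 0:
                keep = (dropout_rng.random(h.shape) >= cfg.dropout) / (1 - cfg.dropout)
                h = h * Tensor(keep)
            layer_outs.append(h)
            if collect_states is not None:
                collect_states.append(h.data.copy())

        jk = concat(layer_outs, axis=1) if cfg.use_jk else layer_outs[-1]

        # readout edge term: (masked) sum of incident encoded edges / degree
        if has_edges:
            he_dir = he.gather(gt.dir_ue)
            if mask_dir is not None:
                he_dir = he_dir * mask_dir.reshape(-1, 1)
            esum = segment_sum(he_dir, gt.dir_src, n)
            denom = np.maximum(gt.deg, 1).astype(np.float64)[:, None]
            edge_term = esum * Tensor(1.0 / denom)
        else:
            edge_term = Tensor(np.zeros((n, cfg.hidden_dim)))

        z = concat([jk, edge_term], axis=1) @ self.params["W_out"] + self.params["b_out"]
        return z.reshape(-1)

    # -- inference ---------------------------------------------------------
    def predict_proba(self, graph) -> np.ndarray:
        gt = graph if isinstance(graph, GraphTensors) else GraphTensors.from_graph(graph)
        z = self.forward(gt)
        return 1.0 / (1.0 + np.exp(-z.data))

    def centrality_encoding(self, degree: int) -> np.ndarray:
        """Learnable embedding row for a (capped) node degree."""
        if degree < 0:
            raise ValueError("degree must be non-negative")
        return self.params["cent_emb"].data[min(degree, self.config.degree_cap)].copy()

    # -- persistence -------------------------------------------------------
    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "params.npz", **{k: v.data for k, v in self.params.items()})
        cfg = asdict(self.config)
        cfg["n_features"] = self.n_features
        with open(out_dir / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1)

    @classmethod
    def load(cls, out_dir) -> "DSBGNN":
        out_dir = Path(out_dir)
        with open(out_dir / "config.json") as fh:
            cfg = json.load(fh)
        n_features = cfg.pop("n_features")
        model = cls(ModelConfig(**cfg), n_features=n_features)
        with np.load(out_dir / "params.npz") as npz:
            for k in model.params:
                model.params[k].data = npz[k]
        return model


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

def loco_split(chrom_ids: Sequence[str], test_chrom: str, val_chrom: str):
    """Leave-one-chromosome-out partition: (train, val, test) chromosome lists."""
    ids = list(chrom_ids)
    if test_chrom not in ids or val_chrom not in ids:
        raise ValueError("test/val chromosome not in chromosome list")
    if test_chrom == val_chrom:
        raise ValueError("test and validation chromosomes must differ")
    train = [c for c in ids if c not in (test_chrom, val_chrom)]
    return train, [val_chrom], [test_chrom]


def _bce_loss(logits: Tensor, labels: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    # softplus(z) - y*z is the stable per-node cross entropy
    y = labels.astype(np.float64)
    w = np.where(y == 1, pos_weight, 1.0)
    per_node = logits.softplus() - logits * Tensor(y)
    return (per_node * Tensor(w)).sum() * (1.0 / w.sum())


def train(graphs: Sequence[ContactGraph], config: ModelConfig) -> DSBGNN:
    """Fit the classifier with full-batch Adam on the cross-entropy loss."""
    gts = [g if isinstance(g, GraphTensors) else GraphTensors.from_graph(g) for g in graphs]
    all_labels = np.concatenate([gt.labels for gt in gts])
    if len(np.unique(all_labels)) < 2:
        raise ValueError("training graphs must contain both DSB and non-DSB nodes")
    model = DSBGNN(config, n_features=gts[0].X.shape[1])
    pos_weight = 1.0
    if config.class_weighting:
        n_pos = all_labels.sum()
        pos_weight = (len(all_labels) - n_pos) / max(n_pos, 1)
    opt = Adam(model.params.values(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    aug_rng = np.random.default_rng(config.seed + 1)
    drng = aug_rng if config.dropout > 0 else None
    for _ in range(config.epochs):
        total = 0.0
        for gt in gts:
            opt.zero_grad()
            x_base = None
            if config.feature_noise > 0:
                noisy = gt.X + aug_rng.normal(0.0, config.feature_noise, gt.X.shape)
                x_base = model.encode_nodes(
                    GraphTensors.from_arrays(noisy, gt.pos, gt.deg, gt.labels,
                                             gt.ue_pairs, gt.ue_count, gt.node_ids))
            logits = model.forward(gt, x_base=x_base, dropout_rng=drng)
            loss = _bce_loss(logits, gt.labels, pos_weight)
            loss.backward()
            opt.step()
            total += float(loss.data)
        model.loss_history.append(total / len(gts))
    return model


def evaluate(model: DSBGNN, graph) -> Tuple[np.ndarray, float]:
    """Per-node probabilities and AUROC on a labeled graph."""
    gt = graph if isinstance(graph, GraphTensors) else GraphTensors.from_graph(graph)
    probs = model.predict_proba(gt)
    return probs, float(roc_auc_score(gt.labels, probs))
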