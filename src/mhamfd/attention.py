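"""The hierarchical attention network over behavioural relation graphs.

Three nested aggregations produce a patient embedding H:

* **intra-relation** — multi-head graph attention over a patient's
  neighbours within one relation graph.  Per head k and relation l, the
  score of neighbour j for target i is
  ``e_ij = LeakyReLU(a_l_k . [W_l_k x_i || W_l_k x_j])`` (slope 0.2),
  normalised by a softmax over the attended set (neighbours plus self);
  head outputs ``sigma(sum_j alpha_ij W_l_k x_j)`` are concatenated to a
  d-dimensional relation embedding (sigma = ELU).
* **inter-relation** — within each level, relation importance
  ``omega_l = mean_i q0 . tanh(W0 x_i^l + b0)`` is softmax-normalised to
  weights beta and the relation embeddings are averaged accordingly.
* **hierarchical** — the level embeddings are combined the same way with
  parameters (q1, W1, b1), giving level weights gamma and the final H.

A linear classifier maps H to fraud/non-fraud logits; training minimises
class-weighted cross-entropy over the labelled nodes, with L2 handled by the
optimiser's weight decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _autodiff as ad
from . import _fastattn as fa
from ._autodiff import Tensor
from .relations import RelationAdjacency, RelationPath

__all__ = [
    "ModelParams",
    "AttentionReport",
    "ForwardResult",
    "init_params",
    "intra_aggregate",
    "inter_aggregate",
    "hierar_aggregate",
    "forward",
    "loss_fn",
    "compute_class_weights",
]

LEAKY_SLOPE = 0.2
LEVEL_NAMES = {1: "single", 2: "dual", 3: "triple"}


def _glorot(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fan_in: int,
    fan_out: int,
    dtype=np.float64,
):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype), requires_grad=True)


@dataclass
class ModelParams:
    """All learnable tensors of the network."""

    relations: list[RelationPath]
    d: int
    d_att: int
    heads: int
    k_in: int
    rel_W: dict[str, Tensor]  # (K, k_in, d_head) per relation
    rel_a_self: dict[str, Tensor]  # (K, d_head, 1)
    rel_a_neigh: dict[str, Tensor]  # (K, d_head, 1)
    W0: Tensor  # (d, d_att)
    b0: Tensor  # (d_att,)
    q0: Tensor  # (d_att, 1)
    W1: Tensor
    b1: Tensor
    q1: Tensor
    Wc: Tensor  # classifier output map ((d or hidden) -> 2)
    Wh: Tensor | None = None  # optional classifier hidden layer (d -> hidden)
    bh: Tensor | None = None

    @property
    def d_head(self) -> int:
        return self.d // self.heads

    def trainable(self) -> list[tuple[Tensor, bool]]:
        """(tensor, weight_decay?) pairs — decay on weights, not biases."""
        out: list[tuple[Tensor, bool]] = []
        for name in (r.name for r in self.relations):
            out += [(self.rel_W[name], True), (self.rel_a_self[name], True),
                    (self.rel_a_neigh[name], True)]
        out += [(self.W0, True), (self.b0, False), (self.q0, True),
                (self.W1, True), (self.b1, False), (self.q1, True), (self.Wc, True)]
        if self.Wh is not None:
            out += [(self.Wh, True), (self.bh, False)]
        return out

    def state(self) -> list[np.ndarray]:
        return [t.data.copy() for t, _ in self.trainable()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        for (t, _), arr in zip(self.trainable(), state):
            t.data = arr.copy()


def init_params(
    k_in: int,
    relations: Sequence[RelationPath],
    d: int = 64,
    d_att: int = 128,
    heads: int = 8,
    seed: int = 0,
    dtype=np.float64,
    classifier_hidden: int = 64,
) -> ModelParams:
    """Glorot-uniform matrices, zero biases; deterministic under ``seed``.

    ``dtype=np.float32`` is the training-loop setting; float64 (default) is
    used wherever exactness matters more than speed.  ``classifier_hidden``
    sizes the hidden layer of the MLP read-out head; 0 gives the plain
    linear classifier.
    """
    if k_in < 1:
        raise ValueError("k_in must be >= 1")
    if d % heads != 0:
        raise ValueError(f"embedding dim {d} not divisible by {heads} heads")
    dh = d // heads
    c_in = classifier_hidden if classifier_hidden else d
    rng = np.random.default_rng(seed)
    rel_W, rel_a_self, rel_a_neigh = {}, {}, {}
    for rel in relations:
        rel_W[rel.name] = _glorot(rng, (heads, k_in, dh), k_in, dh, dtype)
        rel_a_self[rel.name] = _glorot(rng, (heads, dh, 1), 2 * dh, 1, dtype)
        rel_a_neigh[rel.name] = _glorot(rng, (heads, dh, 1), 2 * dh, 1, dtype)
    return ModelParams(
        relations=list(relations),
        d=d,
        d_att=d_att,
        heads=heads,
        k_in=k_in,
        rel_W=rel_W,
        rel_a_self=rel_a_self,
        rel_a_neigh=rel_a_neigh,
        W0=_glorot(rng, (d, d_att), d, d_att, dtype),
        b0=Tensor(np.zeros(d_att, dtype=dtype), requires_grad=True),
        q0=_glorot(rng, (d_att, 1), d_att, 1, dtype),
        W1=_glorot(rng, (d, d_att), d, d_att, dtype),
        b1=Tensor(np.zeros(d_att, dtype=dtype), requires_grad=True),
        q1=_glorot(rng, (d_att, 1), d_att, 1, dtype),
        Wc=_glorot(rng, (c_in, 2), c_in, 2, dtype),
        Wh=(
            _glorot(rng, (d, classifier_hidden), d, classifier_hidden, dtype)
            if classifier_hidden
            else None
        ),
        bh=(
            Tensor(np.zeros(classifier_hidden, dtype=dtype), requires_grad=True)
            if classifier_hidden
            else None
        ),
    )


@dataclass
class AttentionReport:
    """All attention outputs of one forward pass (plain arrays).

    ``alpha[rel]`` is the mean-over-heads neighbour weight matrix (rows sum
    to 1 over each attended set), ``scores[rel]`` the matching pre-softmax
    scores; ``beta``/``omega`` are per-level relation weights/scores and
    ``gamma``/``lam`` the level weights/scores.
    """

    alpha: dict[str, np.ndarray] = field(default_factory=dict)
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    beta: dict[int, np.ndarray] = field(default_factory=dict)
    omega: dict[int, np.ndarray] = field(default_factory=dict)
    relations_by_level: dict[int, list[str]] = field(default_factory=dict)
    gamma: np.ndarray = field(default_factory=lambda: np.array([]))
    lam: np.ndarray = field(default_factory=lambda: np.array([]))
    levels: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        """Two-row summary: level attention and per-relation attention."""
        level_attention = {
            LEVEL_NAMES[lvl]: float(g) for lvl, g in zip(self.levels, self.gamma)
        }
        relation_attention = {}
        for lvl, names in self.relations_by_level.items():
            for name, b in zip(names, self.beta[lvl]):
                relation_attention[name] = float(b)
        return {
            "level_attention": level_attention,
            "relation_attention": relation_attention,
        }


@dataclass
class ForwardResult:
    H: Tensor  # (n, d) final embeddings
    logits: Tensor  # (n, 2)
    report: AttentionReport


def _attention_alpha(s_self: Tensor, s_neigh: Tensor, mask: np.ndarray) -> Tensor:
    """Attention weights softmax_j(LeakyReLU(s_self_i + s_neigh_j)) as one
    fused autodiff node (the hot spot of the whole network)."""
    a = np.ascontiguousarray(s_self.data[:, :, 0])
    b = np.ascontiguousarray(s_neigh.data[:, :, 0])
    p = fa.alpha_forward(a, b, mask, LEAKY_SLOPE)

    def back(g):
        da, db = fa.alpha_backward(a, b, mask, LEAKY_SLOPE, p, np.ascontiguousarray(g))
        if s_self.requires_grad:
            s_self._accumulate(da[:, :, None])
        if s_neigh.requires_grad:
            s_neigh._accumulate(db[:, :, None])

    return Tensor._node(p, (s_self, s_neigh), back)


def intra_aggregate(
    X: Tensor | np.ndarray,
    adj: RelationAdjacency,
    params: ModelParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
    dropout: float = 0.0,
    collect_report: bool = True,
) -> tuple[Tensor, np.ndarray | None, np.ndarray | None]:
    """Multi-head attention over one relation graph.

    Returns the (n, d) relation embedding plus the mean-over-heads attention
    matrix and pre-softmax scores (reported before attention dropout, so
    rows always sum to 1 over the attended set); the two report arrays are
    None when ``collect_report`` is off.
    """
    x = X if isinstance(X, Tensor) else Tensor(X)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("features must be finite")
    name = adj.path.name
    W, a_self, a_neigh = params.rel_W[name], params.rel_a_self[name], params.rel_a_neigh[name]
    mask = adj.attended_mask()  # neighbours + self
    h = x @ W  # (K, n, d_head)
    s_self = h @ a_self  # (K, n, 1)
    s_neigh = h @ a_neigh  # (K, n, 1)
    alpha = _attention_alpha(s_self, s_neigh, mask)  # (K, n, n)
    if collect_report:
        alpha_report = alpha.data.mean(axis=0)
        e = s_self.data[:, :, 0][:, :, None] + s_neigh.data[:, :, 0][:, None, :]
        e = np.where(e > 0, e, LEAKY_SLOPE * e).mean(axis=0)
        score_report = np.where(mask, e, np.nan)
    else:
        alpha_report = score_report = None
    if training and dropout > 0.0:
        alpha = ad.dropout(alpha, dropout, rng)
    out = ad.elu(alpha @ h)  # (K, n, d_head)
    n = x.shape[0]
    emb = out.transpose(1, 0, 2).reshape(n, params.heads * params.d_head)
    return emb, alpha_report, score_report


def _semantic_attention(
    embeds: list[Tensor], W: Tensor, b: Tensor, q: Tensor
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Shared score/softmax/weighted-sum used by both upper aggregations."""
    stacked = ad.stack(embeds, axis=0)  # (m, n, d)
    scores = ad.tanh(stacked @ W + b) @ q  # (m, n, 1)
    w = scores.mean(axis=(1, 2))  # (m,)
    weights = ad.softmax(w, axis=0)
    m = len(embeds)
    combined = (weights.reshape(m, 1, 1) * stacked).sum(axis=0)  # (n, d)
    return combined, weights.data.copy(), w.data.copy()


def inter_aggregate(
    embeddings: Sequence[Tensor], params: ModelParams
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fuse one level's relation embeddings; returns (x_level, beta, omega)."""
    if not embeddings:
        raise ValueError("need at least one relation embedding")
    shapes = {e.shape for e in embeddings}
    if len(shapes) != 1:
        raise ValueError(f"relation embeddings disagree in shape: {shapes}")
    return _semantic_attention(list(embeddings), params.W0, params.b0, params.q0)


def hierar_aggregate(
    level_embeddings: Sequence[Tensor], params: ModelParams
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fuse the level embeddings into H; returns (H, gamma, lambda)."""
    if not level_embeddings:
        raise ValueError("need at least one level embedding")
    shapes = {e.shape for e in level_embeddings}
    if len(shapes) != 1:
        raise ValueError(f"level embeddings disagree in shape: {shapes}")
    return _semantic_attention(list(level_embeddings), params.W1, params.b1, params.q1)


def forward(
    X: np.ndarray,
    levels: Mapping[int, Sequence[RelationAdjacency]],
    params: ModelParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
    dropout: float = 0.0,
    collect_report: bool = True,
) -> ForwardResult:
    """Full pass: intra per relation, inter per level, hierarchical, classifier."""
    if training and dropout > 0.0 and rng is None:
        raise ValueError("training with dropout requires an rng")
    x = X if isinstance(X, Tensor) else Tensor(X)
    if training and dropout > 0.0:
        x = ad.dropout(x, dropout, rng)
    report = AttentionReport()
    level_embeds: list[Tensor] = []
    for lvl in sorted(levels):
        adjs = levels[lvl]
        rel_embeds = []
        for adj in adjs:
            emb, alpha, scores = intra_aggregate(
                x, adj, params, training=training, rng=rng, dropout=dropout,
                collect_report=collect_report,
            )
            rel_embeds.append(emb)
            if collect_report:
                report.alpha[adj.path.name] = alpha
                report.scores[adj.path.name] = scores
        x_level, beta, omega = inter_aggregate(rel_embeds, params)
        report.beta[lvl] = beta
        report.omega[lvl] = omega
        report.relations_by_level[lvl] = [a.path.name for a in adjs]
        level_embeds.append(x_level)
    H, gamma, lam = hierar_aggregate(level_embeds, params)
    report.gamma = gamma
    report.lam = lam
    report.levels = sorted(levels)
    if params.Wh is not None:  # MLP read-out head
        hidden = ad.elu(H @ params.Wh + params.bh)
        if training and dropout > 0.0:
            hidden = ad.dropout(hidden, dropout, rng)
        logits = hidden @ params.Wc
    else:
        logits = H @ params.Wc
    return ForwardResult(H=H, logits=logits, report=report)


def compute_class_weights(
    labels: np.ndarray, mask: np.ndarray, mode: str = "inverse"
) -> np.ndarray:
    """Per-class loss weights: inverse train-frequency, normalised to mean 1."""
    if mode == "none":
        return np.ones(2)
    if mode != "inverse":
        raise ValueError(f"unknown class-weight mode {mode!r}")
    y = labels[mask]
    counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=np.float64)
    if (counts == 0).any():
        return np.ones(2)
    w = counts.sum() / (2.0 * counts)
    return w / w.mean()


def loss_fn(
    logits: Tensor,
    labels: np.ndarray,
    mask: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> Tensor:
    """Class-weighted mean cross-entropy over the masked (labelled) nodes."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = np.flatnonzero(mask)
    if mask.size == 0:
        raise ValueError("loss requires a non-empty labelled mask")
    y = np.asarray(labels)[mask]
    if class_weights is None:
        class_weights = np.ones(2)
    class_weights = np.asarray(class_weights, dtype=np.float64)
    if (class_weights <= 0).any():
        raise ValueError("class weights must be positive")
    logp = ad.log_softmax(ad.take_rows(logits, mask), axis=-1)
    dtype = logp.data.dtype
    onehot = np.zeros((y.size, 2), dtype=dtype)
    onehot[np.arange(y.size), y] = 1.0
    w = class_weights[y].astype(dtype)
    nll = -(logp * onehot).sum(axis=-1)  # (m,)
    return (nll * w).sum() * float(1.0 / w.sum())
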