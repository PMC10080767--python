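"""Semi-supervised training loop, node splits, metrics and the fraud-lift table.

Training is transductive: the whole graph and every patient's features are
visible in each forward pass, but only the training-mask labels enter the
loss.  Early stopping follows the conjunction rule: training stops once
*neither* the validation loss has reached a new minimum *nor* the validation
accuracy a new maximum for ``patience`` consecutive epochs, and the returned
parameters are the ones from the epoch with the lowest validation loss
(earliest on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._autodiff import Adam
from .attention import ModelParams, compute_class_weights, forward, init_params, loss_fn
from .relations import RelationAdjacency, group_by_level

__all__ = [
    "TrainConfig",
    "Metrics",
    "LiftTable",
    "split_nodes",
    "train_model",
    "evaluate",
    "fraud_lift_analysis",
    "features_only_f1",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters; the defaults are the reference settings."""

    lr: float = 0.005
    heads: int = 8
    d: int = 64
    d_att: int = 128
    weight_decay: float = 0.001
    dropout: float = 0.6
    patience: int = 50
    max_epochs: int = 400
    split_ratio: tuple[float, float, float] = (1.0, 1.0, 3.0)
    seed: int = 0
    class_weight_mode: str = "inverse"  # "inverse" | "none"
    classifier_hidden: int = 64  # MLP read-out hidden width; 0 = linear head
    dtype: str = "float32"  # training-loop precision; reports stay float64

    def __post_init__(self):
        if any(r <= 0 for r in self.split_ratio):
            raise ValueError("split ratio parts must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    def with_seed(self, seed: int) -> "TrainConfig":
        return replace(self, seed=seed)


def split_nodes(
    labels: np.ndarray,
    ratio: Sequence[float] = (1.0, 1.0, 3.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/val/test partition of the labelled nodes.

    Returns three boolean masks over all nodes; unlabelled nodes (-1) appear
    in none.  Within each class the labelled nodes are shuffled and split in
    the given proportions by largest remainder, so class balance is kept as
    closely as integer counts allow.
    """
    labels = np.asarray(labels)
    ratio = np.asarray(ratio, dtype=np.float64)
    if ratio.size != 3 or (ratio <= 0).any():
        raise ValueError("ratio must be three positive parts")
    rng = np.random.default_rng(seed)
    masks = [np.zeros(labels.size, dtype=bool) for _ in range(3)]
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"no labelled nodes of class {cls}")
        rng.shuffle(idx)
        exact = ratio / ratio.sum() * idx.size
        counts = np.floor(exact).astype(int)
        order = np.argsort(-(exact - counts))
        for i in range(idx.size - counts.sum()):
            counts[order[i % 3]] += 1
        if (counts == 0).any():
            raise ValueError(
                f"class {cls} would be absent from a split at ratio "
                f"{tuple(ratio)}; use a coarser ratio or more labelled nodes"
            )
        start = 0
        for m, c in zip(masks, counts):
            m[idx[start : start + c]] = True
            start += c
    return masks[0], masks[1], masks[2]


@dataclass
class Metrics:
    """Binary classification metrics with fraud (1) as the positive class."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "warnings": list(self.warnings),
        }


def evaluate(logits: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> Metrics:
    """Confusion-matrix metrics of argmax predictions on the masked nodes.

    Undefined ratios (e.g. precision with no predicted positives) are
    reported as 0 with a warning flag.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = np.flatnonzero(mask)
    if mask.size == 0:
        raise ValueError("evaluation mask is empty")
    logits = np.asarray(getattr(logits, "data", logits))
    pred = logits[mask].argmax(axis=1)
    y = np.asarray(labels)[mask]
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    warnings = []
    if tp + fp == 0:
        precision = 0.0
        warnings.append("no predicted positives: precision undefined, reported as 0")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        warnings.append("no positive labels in mask: recall undefined, reported as 0")
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    if len({0, 1} - set(y.tolist())) > 0:
        warnings.append("mask does not contain both classes")
    return Metrics(
        accuracy=(tp + tn) / mask.size,
        precision=precision,
        recall=recall,
        f1=f1,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        warnings=warnings,
    )


def train_model(
    X: np.ndarray,
    adjacencies: Mapping[str, RelationAdjacency],
    labels: np.ndarray,
    config: TrainConfig = TrainConfig(),
    masks: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[ModelParams, pd.DataFrame]:
    """Fit the network with Adam + weight decay and conjunction early stopping.

    Returns the parameters of the best-validation epoch and a per-epoch
    history frame (train/val loss, val accuracy, best flag).
    """
    dtype = np.dtype(config.dtype).type
    X = np.asarray(X, dtype=dtype)
    labels = np.asarray(labels)
    levels = group_by_level(adjacencies)
    if masks is None:
        masks = split_nodes(labels, config.split_ratio, config.seed)
    train_mask, val_mask, _ = masks
    rng = np.random.default_rng([config.seed, 1])
    relations = [adj.path for adj in adjacencies.values()]
    params = init_params(
        X.shape[1], relations, d=config.d, d_att=config.d_att,
        heads=config.heads, seed=config.seed, dtype=dtype,
        classifier_hidden=config.classifier_hidden,
    )
    weights = compute_class_weights(labels, train_mask, config.class_weight_mode)
    opt = Adam(params.trainable(), lr=config.lr, weight_decay=config.weight_decay)

    best_state = params.state()
    best_val_loss = np.inf
    best_val_acc = -np.inf
    best_epoch = 0
    stall = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        res = forward(
            X, levels, params, training=True, rng=rng, dropout=config.dropout,
            collect_report=False,
        )
        loss = loss_fn(res.logits, labels, train_mask, weights)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        eval_res = forward(X, levels, params, training=False, collect_report=False)
        train_loss_eval = float(loss_fn(eval_res.logits, labels, train_mask, weights).data)
        val_loss = float(loss_fn(eval_res.logits, labels, val_mask, weights).data)
        val_acc = evaluate(eval_res.logits.data, labels, val_mask).accuracy

        improved = False
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            best_state = params.state()
            best_epoch = epoch
            improved = True
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            improved = True
        stall = 0 if improved else stall + 1
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(loss.data),  # dropout-mode objective
                "train_loss_eval": train_loss_eval,  # deterministic forward
                "val_loss": val_loss,
                "val_acc": val_acc,
                "best": epoch == best_epoch,
            }
        )
        if stall >= config.patience:
            break
    params.load_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    return params, history


def features_only_f1(
    X: np.ndarray,
    labels: np.ndarray,
    masks: tuple[np.ndarray, np.ndarray, np.ndarray],
    seed: int = 0,
) -> float:
    """Test F1 of a logistic regression on raw features only.

    The graph-free reference point: with structure-only simulated signal it
    should stay near chance.
    """
    from sklearn.linear_model import LogisticRegression

    train_mask, _, test_mask = masks
    clf = LogisticRegression(max_iter=1000, class_weight="balanced", random_state=seed)
    clf.fit(X[train_mask], labels[train_mask])
    pred = clf.predict(X[test_mask])
    y = labels[test_mask]
    tp = ((pred == 1) & (y == 1)).sum()
    fp = ((pred == 1) & (y == 0)).sum()
    fn = ((pred == 0) & (y == 1)).sum()
    return float(0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn))


@dataclass
class LiftTable:
    """Fraud-rate lift by count of fraudulent neighbours, per relation path.

    ``table[path][bucket]`` holds group size, fraud rate and lift relative
    to the zero-fraud-neighbour group (buckets "0", "1", "2", "3+").  When a
    path has no zero-neighbour patients the overall fraud rate is the
    reference instead and the row is flagged.
    """

    table: dict[str, dict[str, dict[str, float]]]
    flags: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"table": self.table, "flags": dict(self.flags)}

    def to_text(self) -> str:
        lines = [f"{'path':8s} {'bucket':>6s} {'size':>6s} {'rate':>8s} {'lift':>8s}"]
        for path, groups in self.table.items():
            for bucket, row in groups.items():
                lines.append(
                    f"{path:8s} {bucket:>6s} {int(row['size']):>6d} "
                    f"{row['rate']:>8.3f} {row['lift']:>8.3f}"
                )
            if path in self.flags:
                lines.append(f"  [{path}] {self.flags[path]}")
        return "\n".join(lines)


def fraud_lift_analysis(
    adjacencies: Mapping[str, RelationAdjacency], labels: np.ndarray
) -> LiftTable:
    """Group labelled patients by fraudulent-neighbour count and compute lift.

    For each path, labelled patients fall into buckets 0 / 1 / 2 / 3+ by the
    number of labelled-fraud neighbours; each bucket's fraud rate is divided
    by the zero-bucket's rate.
    """
    labels = np.asarray(labels)
    labelled = np.flatnonzero(labels >= 0)
    if not (labels == 1).any():
        raise ValueError("lift analysis requires at least one labelled fraud node")
    table: dict[str, dict[str, dict[str, float]]] = {}
    flags: dict[str, str] = {}
    for name, adj in adjacencies.items():
        counts = np.array(
            [sum(1 for j in adj.neighbors[i] if labels[j] == 1) for i in labelled]
        )
        buckets = {"0": counts == 0, "1": counts == 1, "2": counts == 2, "3+": counts >= 3}
        rates = {}
        for bucket, sel in buckets.items():
            size = int(sel.sum())
            rate = float((labels[labelled[sel]] == 1).mean()) if size else np.nan
            rates[bucket] = {"size": size, "rate": rate}
        zero = rates["0"]
        if zero["size"] > 0 and zero["rate"] > 0:
            ref = zero["rate"]
        else:
            ref = float((labels[labelled] == 1).mean())
            flags[name] = (
                "zero-fraud-neighbour group empty or fraud-free; "
                "lift computed against the overall fraud rate"
            )
        for bucket, row in rates.items():
            row["lift"] = float(row["rate"] / ref) if row["size"] else np.nan
        table[name] = rates
    return LiftTable(table=table, flags=flags)
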