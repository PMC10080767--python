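"""Model/Results interface over the full pipeline.

``MHAMFD`` bundles the data (patient features, relation graphs, labels) with
the hyper-parameters; ``fit()`` runs the semi-supervised training loop and
returns an :class:`MHAMFDResults` carrying the fitted parameters, training
history, per-split metrics, embeddings and the attention report, with a
``summary()`` in the usual fitted-model style.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attention import AttentionReport, ModelParams, forward
from .claims import ClaimRecord, FeatureMatrix, write_json
from .hetero import HeteroGraph, build_hetero_graph, graph_summary
from .relations import RelationAdjacency, build_all_relation_graphs, group_by_level
from .training import (
    LiftTable,
    Metrics,
    TrainConfig,
    evaluate,
    fraud_lift_analysis,
    split_nodes,
    train_model,
)

__all__ = ["MHAMFD", "MHAMFDResults"]


class MHAMFD:
    """Hierarchical-attention fraud-detection model over a claim population.

    Parameters
    ----------
    features
        Per-patient attribute matrix (rows aligned with ``patients``).
    relation_graphs
        Mapping path name -> :class:`RelationAdjacency`; typically the
        output of :func:`mhamfd.relations.build_all_relation_graphs`.
    labels
        Integer vector per patient: 1 fraud, 0 non-fraud, -1 unlabelled.
    config
        Training hyper-parameters (defaults are the reference settings).
    """

    def __init__(
        self,
        features: FeatureMatrix,
        relation_graphs: Mapping[str, RelationAdjacency],
        labels: np.ndarray,
        config: TrainConfig | None = None,
    ):
        self.features = features
        self.relation_graphs = dict(relation_graphs)
        self.labels = np.asarray(labels)
        self.config = config or TrainConfig()
        n = len(features.patient_ids)
        if self.labels.shape != (n,):
            raise ValueError("labels must align with the feature rows")
        for adj in self.relation_graphs.values():
            if adj.n != n:
                raise ValueError("relation adjacency size disagrees with features")
        self.patients = list(features.patient_ids)
        self.graph: HeteroGraph | None = None

    @classmethod
    def from_claims(
        cls,
        claims: Sequence[ClaimRecord],
        features: FeatureMatrix | None = None,
        config: TrainConfig | None = None,
        max_level: int = 3,
        max_neighbors: int | None = None,
    ) -> "MHAMFD":
        """Build graph, relation adjacencies and model straight from claims."""
        g = build_hetero_graph(claims, features)
        adjacencies = build_all_relation_graphs(
            g, max_level=max_level, max_neighbors=max_neighbors,
            seed=(config or TrainConfig()).seed,
        )
        model = cls(g.features, adjacencies, g.labels, config)
        model.graph = g
        return model

    def fit(self, seed: int | None = None) -> "MHAMFDResults":
        """Train and return the fitted results object."""
        config = self.config if seed is None else self.config.with_seed(seed)
        masks = split_nodes(self.labels, config.split_ratio, config.seed)
        params, history = train_model(
            self.features.values, self.relation_graphs, self.labels, config, masks=masks
        )
        levels = group_by_level(self.relation_graphs)
        res = forward(self.features.values, levels, params, training=False)
        metrics = {
            name: evaluate(res.logits.data, self.labels, mask)
            for name, mask in zip(("train", "val", "test"), masks)
        }
        return MHAMFDResults(
            model=self,
            config=config,
            params=params,
            history=history,
            masks={"train": masks[0], "val": masks[1], "test": masks[2]},
            embeddings=res.H.data.copy(),
            logits=res.logits.data.copy(),
            attention=res.report,
            metrics=metrics,
        )


@dataclass
class MHAMFDResults:
    """Fitted-model container: estimates, diagnostics and reports."""

    model: MHAMFD
    config: TrainConfig
    params: ModelParams
    history: pd.DataFrame
    masks: dict[str, np.ndarray]
    embeddings: np.ndarray  # (n, d) final patient embeddings H
    logits: np.ndarray  # (n, 2)
    attention: AttentionReport
    metrics: dict[str, Metrics]

    @property
    def best_epoch(self) -> int:
        return int(self.history.attrs.get("best_epoch", len(self.history)))

    def predict(self) -> np.ndarray:
        """Hard fraud/non-fraud prediction per patient."""
        return self.logits.argmax(axis=1)

    def predict_proba(self) -> np.ndarray:
        """Fraud probability per patient (softmax of the logits)."""
        z = self.logits - self.logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return (e / e.sum(axis=1, keepdims=True))[:, 1]

    def lift_table(self) -> LiftTable:
        return fraud_lift_analysis(self.model.relation_graphs, self.model.labels)

    def summary(self) -> str:
        """Text report: metrics per split, level and relation attention."""
        lines = [
            "MHAMFD fitted model",
            "=" * 55,
            f"patients: {len(self.model.patients)}   "
            f"relations: {len(self.model.relation_graphs)}   "
            f"best epoch: {self.best_epoch}/{len(self.history)}",
            "",
            f"{'split':8s} {'n':>5s} {'acc':>8s} {'prec':>8s} {'recall':>8s} {'f1':>8s}",
        ]
        for name, m in self.metrics.items():
            n = int(self.masks[name].sum())
            lines.append(
                f"{name:8s} {n:>5d} {m.accuracy:>8.4f} {m.precision:>8.4f} "
                f"{m.recall:>8.4f} {m.f1:>8.4f}"
            )
        att = self.attention.as_dict()
        lines += ["", "attention over relationship levels:"]
        for name, v in att["level_attention"].items():
            lines.append(f"  {name:8s} {v:.3f}")
        lines += ["attention over behavioural relationships (within level):"]
        for name, v in att["relation_attention"].items():
            lines.append(f"  {name:8s} {v:.3f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write metrics, attention report, history and embeddings."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(
            {name: m.as_dict() for name, m in self.metrics.items()},
            out / "metrics.json",
        )
        write_json(self.attention.as_dict(), out / "attention.json")
        self.history.to_csv(out / "history.csv", index=False)
        emb = pd.DataFrame(
            self.embeddings, columns=[f"h{i}" for i in range(self.embeddings.shape[1])]
        )
        emb.insert(0, "patient_id", self.model.patients)
        emb.to_csv(out / "embeddings.tsv", sep="\t", index=False)
        if self.model.graph is not None:
            write_json(graph_summary(self.model.graph).as_dict(), out / "graph_summary.json")
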