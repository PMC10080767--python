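"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: the relation
adjacency oracle is an O(n^2 v^2) pairwise-visit scan over claim records,
and the forward oracle is a plain-loop dense-matrix re-implementation of
the network working directly on parameter arrays.
"""

from __future__ import annotations

import numpy as np


def brute_force_neighbors(claims, shared: set[str]) -> dict[str, set[str]]:
    """All-pairs visit scan: patients i, j are neighbours iff some visit of i
    and some visit of j jointly match on every shared entity type."""
    visits = {}
    seen = set()
    for r in claims:
        key = (r.patient_id, r.visit_date, r.department_id, r.medicine_ids)
        if key in seen:
            continue
        seen.add(key)
        visits.setdefault(r.patient_id, []).append(r)
    patients = sorted(visits)
    out = {p: set() for p in patients}
    for i, p in enumerate(patients):
        for q in patients[i + 1 :]:
            hit = False
            for va in visits[p]:
                for vb in visits[q]:
                    ok = True
                    if "D" in shared and va.department_id != vb.department_id:
                        ok = False
                    if ok and "T" in shared and va.visit_date != vb.visit_date:
                        ok = False
                    if ok and "M" in shared and not (va.medicine_ids & vb.medicine_ids):
                        ok = False
                    if ok:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                out[p].add(q)
                out[q].add(p)
    return out


def _leaky(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _softmax(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def dense_intra(X, neighbors, W, a_self, a_neigh):
    """Per-relation multi-head attention, one patient and head at a time."""
    K, _, dh = W.shape
    n = X.shape[0]
    out = np.zeros((n, K * dh))
    alphas = np.zeros((K, n, n))
    for k in range(K):
        h = X @ W[k]
        for i in range(n):
            att = sorted(set(neighbors[i]) | {i})
            scores = np.array(
                [float(a_self[k][:, 0] @ h[i] + a_neigh[k][:, 0] @ h[j]) for j in att]
            )
            alpha = _softmax(_leaky(scores))
            alphas[k, i, att] = alpha
            agg = sum(a * h[j] for a, j in zip(alpha, att))
            out[i, k * dh : (k + 1) * dh] = _elu(agg)
    return out, alphas


def dense_semantic(embeds, W, b, q):
    """Score/softmax/weighted-sum over a list of (n, d) embeddings."""
    scores = np.array([float(np.mean(np.tanh(E @ W + b) @ q)) for E in embeds])
    weights = _softmax(scores)
    combined = sum(w * E for w, E in zip(weights, embeds))
    return combined, weights


def dense_forward(X, adjacencies_by_level, params):
    """Full network pass mirroring the architecture with plain loops.

    ``params`` is a fitted/initialised ModelParams; only its ``.data``
    arrays are read.
    """
    level_embeds = []
    for lvl in sorted(adjacencies_by_level):
        rel_embeds = []
        for adj in adjacencies_by_level[lvl]:
            name = adj.path.name
            emb, _ = dense_intra(
                np.asarray(X, dtype=np.float64),
                adj.neighbors,
                params.rel_W[name].data,
                params.rel_a_self[name].data,
                params.rel_a_neigh[name].data,
            )
            rel_embeds.append(emb)
        x_level, _ = dense_semantic(
            rel_embeds, params.W0.data, params.b0.data, params.q0.data
        )
        level_embeds.append(x_level)
    H, _ = dense_semantic(level_embeds, params.W1.data, params.b1.data, params.q1.data)
    if params.Wh is not None:
        logits = _elu(H @ params.Wh.data + params.bh.data) @ params.Wc.data
    else:
        logits = H @ params.Wc.data
    return H, logits
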