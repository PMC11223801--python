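"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with explicit Python loops and dense
per-node arithmetic, sharing no code with the package's vectorized
gather/scatter path.
"""

from __future__ import annotations

import numpy as np


def dense_layer_forward(layer, h_prev: dict[str, np.ndarray],
                        edges: dict[tuple, np.ndarray]) -> dict[str, np.ndarray]:
    """One HGT layer computed edge by edge, node by node.

    Re-implements: per-head attention score (key/query projections, the
    relation bilinear matrix, the meta-relation prior, 1/sqrt(d_head)
    scaling), softmax over each target's in-neighbors, per-head messages,
    weighted aggregation, output projection, activation and residual.
    """
    h = layer.num_heads
    dh = layer.d_head
    lin = {name: {t: (m.weight.data, m.bias.data) for t, m in getattr(layer, name).items()}
           for name in ("k_lin", "q_lin", "m_lin", "a_lin")}

    def project(name, t, x):
        W, b = lin[name][t]
        return x @ W + b

    # gather every incoming edge per (target type, target node)
    incoming: dict[str, dict[int, list]] = {t: {} for t in h_prev}
    for (st, rel, tt), arr in edges.items():
        key = "::".join((st, rel, tt))
        for s_idx, t_idx in arr:
            incoming[tt].setdefault(int(t_idx), []).append((st, int(s_idx), key))

    out = {}
    for tt, x in h_prev.items():
        n = x.shape[0]
        new = np.zeros((n, layer.d_model))
        for t_idx in range(n):
            q = project("q_lin", tt, h_prev[tt][t_idx]).reshape(h, dh)
            neigh = incoming[tt].get(t_idx, [])
            if neigh:
                scores = np.zeros((len(neigh), h))
                msgs = np.zeros((len(neigh), h, dh))
                for e, (st, s_idx, key) in enumerate(neigh):
                    k = project("k_lin", st, h_prev[st][s_idx]).reshape(h, dh)
                    m = project("m_lin", st, h_prev[st][s_idx]).reshape(h, dh)
                    w_att = layer.w_att[key].data
                    w_msg = layer.w_msg[key].data
                    mu = float(layer.mu[key].data[0])
                    for i in range(h):
                        scores[e, i] = (k[i] @ w_att[i]) @ q[i] * mu / np.sqrt(dh)
                        msgs[e, i] = m[i] @ w_msg[i]
                att = np.exp(scores - scores.max(axis=0))
                att = att / att.sum(axis=0)
                agg = np.zeros((h, dh))
                for e in range(len(neigh)):
                    for i in range(h):
                        agg[i] += att[e, i] * msgs[e, i]
                agg = agg.reshape(layer.d_model)
            else:
                agg = np.zeros(layer.d_model)
            z = project("a_lin", tt, agg)
            act = _gelu(z) if layer.activation == "gelu" else np.maximum(z, 0.0)
            new[t_idx] = act + h_prev[tt][t_idx]
        out[tt] = new
    return out


def _gelu(x):
    from scipy.special import erf
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def auroc_by_pairs(labels, scores) -> float:
    """Concordant-pair AUROC with ties at half weight."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def aupr_by_steps(labels, scores) -> float:
    """Step-wise PR area: sum over positives of precision at their recall step."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    n_pos = labels.sum()
    area = 0.0
    tp = 0
    for k, y in enumerate(labels, start=1):
        if y == 1:
            tp += 1
            area += tp / k
    return area / n_pos


def random_heterograph(rng, max_nodes=10, n_types=3, n_relations=4):
    """A random typed graph as (nodes-per-type, edge dict) for oracle tests."""
    types = [f"t{i}" for i in range(n_types)]
    counts = {t: int(rng.integers(1, max(2, max_nodes // n_types + 1))) for t in types}
    edges = {}
    for r in range(n_relations):
        st, tt = rng.choice(types, size=2, replace=True)
        n_e = int(rng.integers(1, 2 * max(counts[st], counts[tt]) + 1))
        src = rng.integers(0, counts[st], size=n_e)
        dst = rng.integers(0, counts[tt], size=n_e)
        key = (str(st), f"r{r}", str(tt))
        edges[key] = np.column_stack([src, dst]).astype(np.intp)
    return counts, edges
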