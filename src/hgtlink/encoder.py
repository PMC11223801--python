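"""Heterogeneous graph transformer (HGT) encoder.

Each layer computes, per directed edge ``s -> t`` of meta-relation
``(tau(s), phi(e), tau(t))`` and per attention head ``i``:

* attention score  ``(K_i(s) W_att Q_i(t)^T) * mu / sqrt(d_head)`` with
  type-specific key/query projections, a relation-specific bilinear matrix
  ``W_att`` and a learnable scalar meta-relation prior ``mu``;
* message          ``M_i(s) W_msg`` with a type-specific value projection and
  a relation-specific transform;
* softmax over every in-neighbor of ``t`` (per head, across all relations),
  weighted sum of messages, then a target-type output projection, activation
  and residual connection.

The encoder stacks an input projection (ReLU + dropout 0.5 in train mode),
``L`` such layers, and a head that concatenates all layer outputs and maps
them back to ``d_model`` with a ReLU — so nodes expose features from every
receptive-field depth at once.

Defaults follow the repurposing setup: L=3, 8 heads, d_model=64,
input dropout 0.5, GELU activation inside layers (configurable to ReLU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Linear, Module, Tensor, concat, dropout, gather, gelu,
                       heads_matmul, relu, segment_softmax, segment_sum)
from .graph import ConfigurationError, HeteroGraph, Triple


class UnseenRelationError(ConfigurationError):
    """A meta-relation without parameters was encountered in eval mode."""


@dataclass
class EncoderConfig:
    num_layers: int = 3
    d_model: int = 64
    num_heads: int = 8
    dropout_in: float = 0.5
    activation: str = "gelu"      # sigma in the layer update; "relu" also supported
    shared_head: bool = True      # one concat->d_model head for all node types
    auto_instantiate: bool = True  # instantiate params for unseen relations in train mode

    def __post_init__(self):
        if self.num_layers < 1:
            raise ConfigurationError("encoder needs at least one layer")
        if self.d_model % self.num_heads != 0:
            raise ConfigurationError("d_model must be divisible by the head count")
        if not 0.0 <= self.dropout_in <= 1.0:
            raise ConfigurationError("dropout probability must lie in [0, 1]")
        if self.activation not in ("gelu", "relu"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")


def _tk(triple: Triple) -> str:
    return "::".join(triple)


class HGTLayer(Module):
    """One heterogeneous mutual-attention message-passing layer."""

    def __init__(self, node_types, triples, d_model: int, num_heads: int,
                 rng: np.random.Generator, activation: str = "gelu"):
        self.d_model = d_model
        self.num_heads = num_heads
        self.d_head = d_model // num_heads
        self.activation = activation
        self.k_lin = {t: Linear(d_model, d_model, rng) for t in sorted(node_types)}
        self.q_lin = {t: Linear(d_model, d_model, rng) for t in sorted(node_types)}
        self.m_lin = {t: Linear(d_model, d_model, rng) for t in sorted(node_types)}
        self.a_lin = {t: Linear(d_model, d_model, rng) for t in sorted(node_types)}
        self.w_att: dict[str, Tensor] = {}
        self.w_msg: dict[str, Tensor] = {}
        self.mu: dict[str, Tensor] = {}
        self.ensure_relations(triples, rng)

    def ensure_relations(self, triples, rng: np.random.Generator) -> None:
        """Create relation-keyed parameters for any triple lacking them."""
        h, dh = self.num_heads, self.d_head
        bound = 1.0 / np.sqrt(dh)
        for triple in sorted(triples):
            key = _tk(triple)
            if key in self.w_att:
                continue
            self.w_att[key] = Tensor(rng.uniform(-bound, bound, (h, dh, dh)),
                                     requires_grad=True)
            self.w_msg[key] = Tensor(rng.uniform(-bound, bound, (h, dh, dh)),
                                     requires_grad=True)
            # prior initialized at 1: no relation favored before training
            self.mu[key] = Tensor(np.ones(1), requires_grad=True)

    def _act(self, x: Tensor) -> Tensor:
        return gelu(x) if self.activation == "gelu" else relu(x)

    def _check(self, edges: dict, rng, train: bool) -> None:
        # zero-edge triples never need parameters (and must not consume rng)
        missing = [t for t, arr in edges.items() if len(arr) and _tk(t) not in self.w_att]
        if missing:
            if train and rng is not None:
                self.ensure_relations(missing, rng)
            else:
                raise UnseenRelationError(f"no parameters for meta-relation(s) {missing}")

    # -- exposed sub-operations (eval-mode numpy views) --------------------
    def attention_coefficients(self, h_prev: dict[str, np.ndarray],
                               edges: dict[Triple, np.ndarray]) -> dict[Triple, np.ndarray]:
        """Per-edge per-head attention weights, softmax-normalized over each
        target node's in-neighbors (across relations)."""
        _, att, _, _ = self._edge_pass({t: Tensor(x) for t, x in h_prev.items()}, edges)
        return {t: w.data for t, w in att.items()}

    def messages(self, h_prev: dict[str, np.ndarray],
                 edges: dict[Triple, np.ndarray]) -> dict[Triple, np.ndarray]:
        """Per-edge message vectors ``(E, num_heads, d_head)``; reshaping to
        ``(E, d_model)`` is the head concatenation."""
        _, _, msgs, _ = self._edge_pass({t: Tensor(x) for t, x in h_prev.items()}, edges)
        return {t: m.data for t, m in msgs.items()}

    # -- full layer --------------------------------------------------------
    def _edge_pass(self, H: dict[str, Tensor], edges: dict[Triple, np.ndarray]):
        """Scores, normalized attention, messages and dst indices per triple."""
        h, dh = self.num_heads, self.d_head
        K, M, Q = {}, {}, {}
        for t, x in H.items():
            n = x.shape[0]
            K[t] = self.k_lin[t](x).reshape(n, h, dh)
            M[t] = self.m_lin[t](x).reshape(n, h, dh)
            Q[t] = self.q_lin[t](x).reshape(n, h, dh)
        raw: dict[Triple, Tensor] = {}
        msgs: dict[Triple, Tensor] = {}
        for triple, arr in edges.items():
            if len(arr) == 0:
                continue
            st, _, tt = triple
            key = _tk(triple)
            src, dst = arr[:, 0], arr[:, 1]
            kw = heads_matmul(gather(K[st], src), self.w_att[key])
            score = (kw * gather(Q[tt], dst)).sum(axis=2) \
                * (self.mu[key] * (1.0 / np.sqrt(dh)))
            raw[triple] = score
            msgs[triple] = heads_matmul(gather(M[st], src), self.w_msg[key])
        # softmax per target node across every incoming relation
        att: dict[Triple, Tensor] = {}
        by_target: dict[str, list[Triple]] = {}
        for triple in raw:
            by_target.setdefault(triple[2], []).append(triple)
        for tt, trs in by_target.items():
            n = H[tt].shape[0]
            scores = concat([raw[t] for t in trs], axis=0)
            dsts = np.concatenate([edges[t][:, 1] for t in trs])
            w = segment_softmax(scores, dsts, n)
            offset = 0
            for t in trs:
                e = len(edges[t])
                att[t] = _slice_rows(w, offset, offset + e)
                offset += e
        dsts = {t: edges[t][:, 1] for t in raw}
        return raw, att, msgs, dsts

    def aggregate(self, att: dict[Triple, Tensor], msgs: dict[Triple, Tensor],
                  dsts: dict[Triple, np.ndarray], H: dict[str, Tensor]) -> dict[str, Tensor]:
        """Attention-weighted message sum, output projection, activation,
        residual.  Nodes with no in-neighbors aggregate the zero vector."""
        h = self.num_heads
        H_new = {}
        for tt, x in H.items():
            n = x.shape[0]
            parts_m = [msgs[t] for t in msgs if t[2] == tt]
            if parts_m:
                m = concat(parts_m, axis=0)
                w = concat([_as_tensor(att[t]) for t in msgs if t[2] == tt], axis=0)
                d = np.concatenate([dsts[t] for t in msgs if t[2] == tt])
                weighted = m * w.reshape(w.shape[0], h, 1)
                agg = segment_sum(weighted, d, n).reshape(n, self.d_model)
            else:
                agg = Tensor(np.zeros((n, self.d_model)))
            H_new[tt] = self._act(self.a_lin[tt](agg)) + x
        return H_new

    def __call__(self, H: dict[str, Tensor], edges: dict[Triple, np.ndarray],
                 train: bool = False, rng: np.random.Generator | None = None
                 ) -> dict[str, Tensor]:
        self._check(edges, rng, train)
        _, att, msgs, dsts = self._edge_pass(H, edges)
        return self.aggregate(att, msgs, dsts, H)


def _slice_rows(x: Tensor, lo: int, hi: int) -> Tensor:
    return gather(x, np.arange(lo, hi))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class HGTEncoder(Module):
    """Input projection + L HGT layers + multi-depth concatenation head."""

    def __init__(self, cfg: EncoderConfig, input_dims: dict[str, int],
                 triples, rng: np.random.Generator):
        self.cfg = cfg
        self.node_types = sorted(input_dims)
        self.input_dims = dict(input_dims)
        self.triples = sorted(triples)
        self.input_proj = {t: Linear(input_dims[t], cfg.d_model, rng)
                           for t in self.node_types}
        self.layers = [HGTLayer(self.node_types, self.triples, cfg.d_model,
                                cfg.num_heads, rng, cfg.activation)
                       for _ in range(cfg.num_layers)]
        if cfg.shared_head:
            self.head = Linear(cfg.num_layers * cfg.d_model, cfg.d_model, rng)
        else:
            self.head = {t: Linear(cfg.num_layers * cfg.d_model, cfg.d_model, rng)
                         for t in self.node_types}

    @classmethod
    def for_graph(cls, g: HeteroGraph, cfg: EncoderConfig,
                  rng: np.random.Generator) -> "HGTEncoder":
        """Build an encoder whose parameters cover ``g`` (with reverse
        relations materialized so messages flow both ways)."""
        gv = g.with_reverse_relations()
        if not g.embeddings:
            raise ConfigurationError("graph carries no initial embeddings")
        dims = {t: g.embeddings[t].shape[1] for t in g.nodes}
        triples = [t for t in gv.triples if gv.num_edges(t) > 0]
        return cls(cfg, dims, triples, rng)

    def project_input(self, h_init: dict[str, np.ndarray], train: bool = False,
                      rng: np.random.Generator | None = None) -> dict[str, Tensor]:
        """ReLU(Linear_tau(H_init)) with dropout in train mode."""
        out = {}
        for t, x in h_init.items():
            x = _as_tensor(x)
            if x.shape[1] != self.input_dims[t]:
                raise ConfigurationError(
                    f"input dim mismatch for type {t!r}: got {x.shape[1]}, "
                    f"expected {self.input_dims[t]}")
            y = relu(self.input_proj[t](x))
            if train:
                if rng is None:
                    raise ConfigurationError("train-mode projection needs an rng for dropout")
                y = dropout(y, self.cfg.dropout_in, rng, train=True)
            out[t] = y
        return out

    def encode(self, g: HeteroGraph, train: bool = False,
               rng: np.random.Generator | None = None) -> dict[str, Tensor]:
        """Node features for every node of ``g`` (``Feat``, width d_model)."""
        gv = g.with_reverse_relations()
        if not gv.embeddings:
            raise ConfigurationError("graph carries no initial embeddings")
        edges = {t: a for t, a in gv.edges.items()}
        H = self.project_input({t: gv.embeddings[t] for t in gv.nodes}, train, rng)
        per_layer = []
        for layer in self.layers:
            H = layer(H, edges, train=train, rng=rng)
            per_layer.append(H)
        feat = {}
        for t in H:
            stacked = concat([per_layer[l][t] for l in range(len(self.layers))], axis=1)
            head = self.head if self.cfg.shared_head else self.head[t]
            feat[t] = relu(head(stacked))
        return feat
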