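"""Heterogeneous knowledge-graph data model and edge-table I/O.

A :class:`HeteroGraph` stores typed nodes and directed typed edges.  Every
edge belongs to a *meta-relation* ``(source type, relation name, target
type)``; encoder and sampler parameters are keyed by these triples.  Node
identifiers live in a per-type namespace, so the same raw id may appear under
two types without colliding.

The reader speaks the PrimeKG edge-table dialect (one CSV row per directed
edge with relation / endpoint-type / endpoint-id columns) and a generic
dialect with configurable column names.  Target-relation edges — drug–disease
indications in the repurposing task — are manipulated as unordered id pairs:
masking or holding out a pair removes every stored orientation of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class GraphError(Exception):
    """Base class for graph construction and manipulation errors."""


class FormatError(GraphError):
    """Malformed input file (missing column, ragged row, non-numeric cell)."""


class SchemaError(GraphError):
    """Row references a node type outside the declared type set."""


class EmptyGraphError(GraphError):
    """The edge table contains no rows."""


class ConfigurationError(GraphError):
    """A referenced relation or option does not exist."""


class MissingNodeError(GraphError, KeyError):
    """A referenced node id does not exist under the given type."""


Triple = tuple[str, str, str]
REVERSE_PREFIX = "rev__"


@dataclass
class Dialect:
    """Column mapping for an edge-table CSV."""

    relation: str = "relation"
    src_type: str = "x_type"
    src_id: str = "x_id"
    dst_type: str = "y_type"
    dst_id: str = "y_id"
    src_name: str | None = "x_name"
    dst_name: str | None = "y_name"

    @property
    def required(self) -> list[str]:
        return [self.relation, self.src_type, self.src_id, self.dst_type, self.dst_id]


PRIMEKG_DIALECT = Dialect()


class HeteroGraph:
    """Typed nodes plus directed typed edges stored as index arrays.

    Parameters
    ----------
    nodes:
        Mapping node type -> ordered sequence of node identifiers.
    edges:
        Mapping meta-relation triple -> ``(E, 2)`` integer array of
        (source index, target index) into the respective type's node list.
    node_names:
        Optional mapping node type -> {id: display name}.
    embeddings:
        Optional mapping node type -> ``(n_type, dim)`` float array of initial
        node features, row-aligned with ``nodes[type]``.
    """

    def __init__(self, nodes: Mapping[str, Sequence], edges: Mapping[Triple, np.ndarray],
                 node_names: Mapping[str, Mapping] | None = None,
                 embeddings: Mapping[str, np.ndarray] | None = None):
        self.nodes: dict[str, list] = {t: list(ids) for t, ids in nodes.items()}
        self.edges: dict[Triple, np.ndarray] = {}
        self.node_names = {t: dict(m) for t, m in node_names.items()} if node_names else {}
        self.embeddings = dict(embeddings) if embeddings else {}
        self._index_cache: dict[str, dict] = {}
        for t, ids in self.nodes.items():
            if len(set(ids)) != len(ids):
                raise SchemaError(f"duplicate node identifiers within type {t!r}")
        for triple, arr in edges.items():
            st, rel, tt = triple
            arr = np.asarray(arr, dtype=np.intp).reshape(-1, 2)
            for side, typ in ((0, st), (1, tt)):
                if typ not in self.nodes:
                    raise SchemaError(f"relation {rel!r} references unknown type {typ!r}")
                if arr.size and (arr[:, side].min() < 0 or arr[:, side].max() >= len(self.nodes[typ])):
                    raise SchemaError(f"edge index out of range for type {typ!r} in {triple}")
            self.edges[triple] = arr

    # -- basic accessors ---------------------------------------------------
    @property
    def node_types(self) -> set[str]:
        return set(self.nodes)

    @property
    def relation_names(self) -> set[str]:
        return {rel for (_, rel, _) in self.edges}

    @property
    def triples(self) -> list[Triple]:
        return list(self.edges)

    def num_nodes(self, node_type: str | None = None) -> int:
        if node_type is None:
            return sum(len(v) for v in self.nodes.values())
        return len(self.nodes.get(node_type, ()))

    def num_edges(self, key: Triple | str | None = None) -> int:
        if key is None:
            return sum(len(a) for a in self.edges.values())
        if isinstance(key, str):
            return sum(len(a) for t, a in self.edges.items() if t[1] == key)
        return len(self.edges.get(key, ()))

    def node_index(self, node_type: str) -> dict:
        if node_type not in self._index_cache:
            self._index_cache[node_type] = {v: i for i, v in enumerate(self.nodes[node_type])}
        return self._index_cache[node_type]

    def triples_for(self, relation: str) -> list[Triple]:
        out = [t for t in self.edges if t[1] == relation]
        if not out:
            raise ConfigurationError(f"relation {relation!r} not present in graph")
        return out

    def edge_ids(self, triple: Triple) -> list[tuple]:
        """Edges of a meta-relation as (source id, target id) pairs."""
        st, _, tt = triple
        src, dst = self.nodes[st], self.nodes[tt]
        return [(src[i], dst[j]) for i, j in self.edges[triple]]

    # -- target-relation pairs --------------------------------------------
    def endpoint_types(self, relation: str) -> tuple[str, str]:
        """The (source, target) type pair of a relation, canonically oriented.

        All triples carrying the relation must connect the same unordered type
        pair; for bipartite relations the orientation of the first stored
        triple wins, for self-paired relations both types coincide.
        """
        trs = self.triples_for(relation)
        pairs = {frozenset((st, tt)) for st, _, tt in trs}
        if len(pairs) != 1:
            raise ConfigurationError(
                f"relation {relation!r} connects multiple type pairs: {sorted(trs)}")
        return trs[0][0], trs[0][2]

    def relation_pairs(self, relation: str) -> set[tuple]:
        """Unordered id pairs of a relation, canonicalized to (src, dst) of
        :meth:`endpoint_types`; self-pairs of self-paired relations excluded."""
        st, tt = self.endpoint_types(relation)
        pairs: set[tuple] = set()
        for triple in self.triples_for(relation):
            for a, b in self.edge_ids(triple):
                if triple[0] != st:  # stored in the reverse orientation
                    a, b = b, a
                if st == tt:
                    if a == b:
                        continue
                    a, b = sorted((a, b), key=repr)
                pairs.add((a, b))
        return pairs

    # -- derived graphs ----------------------------------------------------
    def _copy_with_edges(self, edges: Mapping[Triple, np.ndarray]) -> "HeteroGraph":
        return HeteroGraph(self.nodes, edges, self.node_names, self.embeddings)

    def without_relation(self, relation: str) -> "HeteroGraph":
        self.triples_for(relation)  # raises ConfigurationError if absent
        return self._copy_with_edges(
            {t: a for t, a in self.edges.items() if t[1] != relation})

    def without_pairs(self, relation: str, pairs: Iterable[tuple]) -> "HeteroGraph":
        """Drop every stored orientation of the given unordered id pairs."""
        st, tt = self.endpoint_types(relation)
        drop = set()
        for a, b in pairs:
            drop.add((a, b))
            drop.add((b, a))
        new_edges = dict(self.edges)
        for triple in self.triples_for(relation):
            t_src, _, t_dst = triple
            src_ids, dst_ids = self.nodes[t_src], self.nodes[t_dst]
            arr = self.edges[triple]
            keep = np.array([(src_ids[i], dst_ids[j]) not in drop for i, j in arr], dtype=bool) \
                if len(arr) else np.zeros(0, dtype=bool)
            new_edges[triple] = arr[keep]
        return self._copy_with_edges(new_edges)

    def with_reverse_relations(self) -> "HeteroGraph":
        """Materialize a reverse relation for any triple whose opposite
        orientation is not already stored, so messages can flow both ways."""
        new_edges = dict(self.edges)
        for (st, rel, tt), arr in self.edges.items():
            if rel.startswith(REVERSE_PREFIX):
                continue
            if (tt, rel, st) in self.edges and (st != tt):
                continue
            rev = (tt, REVERSE_PREFIX + rel, st)
            new_edges[rev] = arr[:, ::-1].copy()
        return self._copy_with_edges(new_edges)

    def subgraph(self, selection: Mapping[str, Iterable]) -> "HeteroGraph":
        """Induced subgraph on the selected ids (absent types keep no nodes)."""
        new_nodes: dict[str, list] = {}
        keep_mask: dict[str, np.ndarray] = {}
        remap: dict[str, np.ndarray] = {}
        for t, ids in self.nodes.items():
            sel = selection.get(t, ())
            sel_set = set(sel)
            unknown = sel_set - set(ids)
            if unknown:
                raise MissingNodeError(
                    f"unknown {t!r} node id(s): {sorted(map(repr, unknown))[:5]}")
            mask = np.array([v in sel_set for v in ids], dtype=bool)
            keep_mask[t] = mask
            new_nodes[t] = [v for v, m in zip(ids, mask) if m]
            r = np.full(len(ids), -1, dtype=np.intp)
            r[mask] = np.arange(mask.sum())
            remap[t] = r
        new_edges = {}
        for (st, rel, tt), arr in self.edges.items():
            if len(arr) == 0:
                new_edges[(st, rel, tt)] = arr.copy()
                continue
            m = keep_mask[st][arr[:, 0]] & keep_mask[tt][arr[:, 1]]
            kept = arr[m]
            new_edges[(st, rel, tt)] = np.column_stack(
                [remap[st][kept[:, 0]], remap[tt][kept[:, 1]]]) if len(kept) \
                else np.zeros((0, 2), dtype=np.intp)
        names = {t: {v: self.node_names[t][v] for v in new_nodes[t] if v in self.node_names[t]}
                 for t in self.node_names}
        emb = {t: self.embeddings[t][keep_mask[t]] for t in self.embeddings}
        return HeteroGraph(new_nodes, new_edges, names, emb)

    def with_embeddings(self, embeddings: Mapping[str, np.ndarray]) -> "HeteroGraph":
        return HeteroGraph(self.nodes, self.edges, self.node_names, embeddings)

    def degrees(self, node_type: str) -> np.ndarray:
        """Total degree per node of a type, counting both edge directions."""
        deg = np.zeros(self.num_nodes(node_type), dtype=np.intp)
        for (st, _, tt), arr in self.edges.items():
            if len(arr) == 0:
                continue
            if st == node_type:
                np.add.at(deg, arr[:, 0], 1)
            if tt == node_type:
                np.add.at(deg, arr[:, 1], 1)
        return deg


# -- indication split and folds --------------------------------------------

@dataclass
class IndicationSplit:
    """Partition of a target relation's unordered pairs.

    ``unmasked`` pairs stay in the input graph; ``masked`` pairs are the
    training positives (absent from the graph view, predicted from context);
    ``validation`` pairs are a held-out fold; ``negatives`` carry label 0 and
    intersect none of the positives.
    """

    target_relation: str
    endpoint_types: tuple[str, str]
    unmasked: set = field(default_factory=set)
    masked: set = field(default_factory=set)
    validation: set = field(default_factory=set)
    negatives: set = field(default_factory=set)

    def __post_init__(self):
        groups = [self.unmasked, self.masked, self.validation]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] & groups[j]:
                    raise ConfigurationError("split groups must be pairwise disjoint")
        if self.negatives & self.positives:
            raise ConfigurationError("negatives must not intersect positive pairs")

    @property
    def positives(self) -> set:
        return self.unmasked | self.masked | self.validation

    def labels(self) -> dict[tuple, int]:
        out = {p: 1 for p in self.positives}
        out.update({p: 0 for p in self.negatives})
        return out

    def apply(self, g: HeteroGraph) -> HeteroGraph:
        """Graph view without masked and validation edges."""
        hidden = self.masked | self.validation
        return g.without_pairs(self.target_relation, hidden) if hidden else g


@dataclass
class FoldPlan:
    """Seed-reproducible k-fold partition of a pair set."""

    k: int
    assignments: dict[tuple, int]
    seed: int

    def fold(self, i: int) -> set:
        return {p for p, f in self.assignments.items() if f == i}

    def sizes(self) -> list[int]:
        out = [0] * self.k
        for f in self.assignments.values():
            out[f] += 1
        return out


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_indications(g: HeteroGraph, target_relation: str, mask_fraction: float,
                      rng_seed: int, validation: Iterable[tuple] = ()) -> IndicationSplit:
    """Split target pairs into masked training positives and unmasked graph edges.

    ``mask_fraction`` of the non-validation pairs are masked
    (round-half-away-from-zero); ``validation`` pairs, if given, are excluded
    from both groups and recorded on the split.
    """
    if not 0.0 <= mask_fraction <= 1.0:
        raise ConfigurationError("mask_fraction must lie in [0, 1]")
    endpoint = g.endpoint_types(target_relation)
    all_pairs = g.relation_pairs(target_relation)
    validation = set(validation)
    stray = validation - all_pairs
    if stray:
        raise ConfigurationError(f"validation pairs not in target relation: {sorted(stray)[:3]}")
    pool = sorted(all_pairs - validation, key=repr)
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    rng.shuffle(pool)
    n_mask = _round_half_away(mask_fraction * len(pool))
    masked = set(pool[:n_mask])
    unmasked = set(pool[n_mask:])
    return IndicationSplit(target_relation, endpoint, unmasked=unmasked,
                           masked=masked, validation=validation)


def make_folds(pairs: Iterable[tuple], k: int, rng_seed: int) -> FoldPlan:
    """Partition pairs into k seed-reproducible folds with sizes differing <= 1."""
    pairs = sorted(set(pairs), key=repr)
    if k < 2:
        raise ConfigurationError("fold count k must be >= 2")
    if len(pairs) < k:
        raise ConfigurationError(f"need at least k={k} pairs, got {len(pairs)}")
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    rng.shuffle(pairs)
    assignments = {p: i % k for i, p in enumerate(pairs)}
    return FoldPlan(k=k, assignments=assignments, seed=rng_seed)


# -- node filtering ---------------------------------------------------------

def filter_unindicated(g: HeteroGraph, target_relation: str) -> HeteroGraph:
    """Drop endpoint-type nodes that touch no target-relation edge.

    Mirrors the construction step that removes drugs and diseases without any
    indication, so the prediction task cannot be padded with trivially
    unlinkable nodes.  Nodes of other types are untouched; edges incident to
    removed nodes disappear with them.  Idempotent.
    """
    st, tt = g.endpoint_types(target_relation)
    keep: dict[str, set] = {st: set(), tt: set()}
    for triple in g.triples_for(target_relation):
        for a, b in g.edge_ids(triple):
            keep[triple[0]].add(a)
            keep[triple[2]].add(b)
    selection = {t: (keep[t] if t in keep else list(ids)) for t, ids in g.nodes.items()}
    return g.subgraph(selection)


def induce_subgraph(g: HeteroGraph, selection: Mapping[str, Iterable]) -> HeteroGraph:
    """Induced subgraph on per-type node id sets (functional alias)."""
    return g.subgraph(selection)


def remove_relation(g: HeteroGraph, relation: str) -> HeteroGraph:
    """Drop every edge of a relation; nodes and other relations untouched."""
    return g.without_relation(relation)


# -- edge-table I/O ----------------------------------------------------------

def load_edge_table(path, dialect: Dialect = PRIMEKG_DIALECT,
                    node_types: Iterable[str] | None = None,
                    deduplicate: bool = True,
                    allow_self_loops: bool = False) -> HeteroGraph:
    """Read a PrimeKG-dialect edge CSV into a :class:`HeteroGraph`.

    Exact duplicate (relation, endpoint) rows are collapsed by default and
    self-loops dropped; ``node_types``, if given, declares the admissible type
    set and any other type raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required if c not in df.columns]
    if missing:
        raise FormatError(f"edge table missing required column(s): {missing}")
    if len(df) == 0:
        raise EmptyGraphError(f"edge table {path} contains no rows")
    if node_types is not None:
        declared = set(node_types)
        seen = set(df[dialect.src_type]) | set(df[dialect.dst_type])
        bad = seen - declared
        if bad:
            raise SchemaError(f"undeclared node type(s) in edge table: {sorted(bad)}")
    if deduplicate:
        df = df.drop_duplicates(subset=dialect.required)
    if not allow_self_loops:
        loop = (df[dialect.src_type] == df[dialect.dst_type]) \
            & (df[dialect.src_id] == df[dialect.dst_id])
        df = df[~loop]
    nodes: dict[str, list] = {}
    index: dict[str, dict] = {}
    names: dict[str, dict] = {}

    def intern(t: str, i: str, name: str | None) -> int:
        idx = index.setdefault(t, {})
        if i not in idx:
            idx[i] = len(idx)
            nodes.setdefault(t, []).append(i)
        if name:
            names.setdefault(t, {})[i] = name
        return idx[i]

    edges: dict[Triple, list] = {}
    has_src_name = dialect.src_name in df.columns if dialect.src_name else False
    has_dst_name = dialect.dst_name in df.columns if dialect.dst_name else False
    cols = [dialect.relation, dialect.src_type, dialect.src_id, dialect.dst_type, dialect.dst_id]
    name_cols = [dialect.src_name if has_src_name else dialect.relation,
                 dialect.dst_name if has_dst_name else dialect.relation]
    for rel, st, sid, tt, tid, sn, tn in df[cols + name_cols].itertuples(index=False):
        i = intern(st, sid, sn if has_src_name else None)
        j = intern(tt, tid, tn if has_dst_name else None)
        edges.setdefault((st, rel, tt), []).append((i, j))
    return HeteroGraph(nodes, {k: np.asarray(v, dtype=np.intp) for k, v in edges.items()},
                       names or None)


def write_edge_table(g: HeteroGraph, path, dialect: Dialect = PRIMEKG_DIALECT) -> None:
    """Write the graph back to an edge CSV (inverse of :func:`load_edge_table`)."""
    rows = []
    for (st, rel, tt), arr in g.edges.items():
        if rel.startswith(REVERSE_PREFIX):
            continue
        src, dst = g.nodes[st], g.nodes[tt]
        sn = g.node_names.get(st, {})
        tn = g.node_names.get(tt, {})
        for i, j in arr:
            row = {dialect.relation: rel, dialect.src_type: st, dialect.src_id: src[i],
                   dialect.dst_type: tt, dialect.dst_id: dst[j]}
            if dialect.src_name:
                row[dialect.src_name] = sn.get(src[i], "")
            if dialect.dst_name:
                row[dialect.dst_name] = tn.get(dst[j], "")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def split_to_table(split: IndicationSplit, folds: FoldPlan | None = None) -> pd.DataFrame:
    """Tabular export of a split: (drug id, disease id, role, fold)."""
    rows = []
    for role, pairs in (("unmasked", split.unmasked), ("masked", split.masked),
                        ("validation", split.validation), ("negative", split.negatives)):
        for a, b in sorted(pairs, key=repr):
            fold = folds.assignments.get((a, b), -1) if folds else -1
            rows.append({"drug": a, "disease": b, "role": role, "fold": fold})
    return pd.DataFrame(rows, columns=["drug", "disease", "role", "fold"])
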