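"""Initial per-node feature vectors.

Named entities typically carry text-model embeddings and drugs carry
molecule-model embeddings of their structure strings; different node types may
use different dimensions.  This module only *consumes* such tables (CSV/TSV:
id column + numeric columns) and provides a seeded standard-normal fallback
initializer so the pipeline runs without any pretrained model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import ConfigurationError, FormatError, HeteroGraph

DEFAULT_DIM = 768  # width of the language-model embeddings consumed by default


class MissingEmbeddingError(ConfigurationError):
    """A node has no vector and the strict policy is in force."""


@dataclass
class EmbeddingTable:
    """id -> vector table for one node type; all vectors share ``dim``."""

    node_type: str
    dim: int
    vectors: dict

    def __post_init__(self):
        for k, v in self.vectors.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (self.dim,):
                raise FormatError(
                    f"vector for {self.node_type!r} id {k!r} has length {v.shape}, "
                    f"expected ({self.dim},)")
            self.vectors[k] = v


def random_embeddings(g: HeteroGraph, dim_per_type: dict[str, int],
                      rng_seed: int) -> dict[str, EmbeddingTable]:
    """Seeded standard-normal tables for every node type in ``dim_per_type``."""
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    tables = {}
    for t in sorted(dim_per_type):
        dim = dim_per_type[t]
        if dim <= 0:
            raise ConfigurationError(f"embedding dim for type {t!r} must be positive")
        ids = g.nodes.get(t, [])
        mat = rng.standard_normal((len(ids), dim))
        tables[t] = EmbeddingTable(t, dim, {i: mat[k] for k, i in enumerate(ids)})
    return tables


def attach_embeddings(g: HeteroGraph, tables: dict[str, EmbeddingTable],
                      policy: str = "strict", rng_seed: int = 0) -> HeteroGraph:
    """Return a copy of ``g`` carrying per-type feature matrices.

    Every node type of the graph needs a table.  Under ``policy="strict"``
    any node without a vector is an error; ``policy="impute-random"`` fills
    gaps with seeded standard-normal vectors instead.  Topology is untouched.
    """
    if policy not in ("strict", "impute-random"):
        raise ConfigurationError(f"unknown missing-value policy {policy!r}")
    missing_types = set(g.nodes) - set(tables)
    if missing_types:
        raise MissingEmbeddingError(f"no embedding table for type(s) {sorted(missing_types)}")
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    embeddings = {}
    for t, ids in g.nodes.items():
        table = tables[t]
        unknown = set(table.vectors) - set(ids)
        if unknown:
            raise MissingEmbeddingError(
                f"embedding table for {t!r} keys id {sorted(map(repr, unknown))[0]} "
                f"not present in graph")
        gaps = [i for i in ids if i not in table.vectors]
        if gaps and policy == "strict":
            raise MissingEmbeddingError(
                f"{len(gaps)} node(s) of type {t!r} lack embeddings, e.g. "
                f"{sorted(map(repr, gaps))[:5]}")
        mat = np.empty((len(ids), table.dim))
        for k, i in enumerate(ids):
            mat[k] = table.vectors[i] if i in table.vectors \
                else rng.standard_normal(table.dim)
        embeddings[t] = mat
    return g.with_embeddings(embeddings)


def load_embedding_file(path, node_type: str, sep: str = ",",
                        header: bool = True) -> EmbeddingTable:
    """Read an id + numeric-columns table; dim = column count - 1."""
    try:
        df = pd.read_csv(path, sep=sep, header=0 if header else None, dtype=str,
                         keep_default_na=False)
    except pd.errors.ParserError as e:  # ragged rows
        raise FormatError(f"malformed embedding file {path}: {e}") from e
    if df.shape[1] < 2:
        raise FormatError(f"embedding file {path} needs an id column plus >=1 numeric column")
    ids = df.iloc[:, 0].tolist()
    try:
        mat = df.iloc[:, 1:].astype(np.float64).to_numpy()
    except ValueError as e:
        raise FormatError(f"non-numeric cell in embedding file {path}: {e}") from e
    if np.isnan(mat).any():
        row = int(np.argwhere(np.isnan(mat))[0, 0]) + 1
        raise FormatError(f"missing value in embedding file {path} at data row {row}")
    dim = mat.shape[1]
    return EmbeddingTable(node_type, dim, {i: mat[k] for k, i in enumerate(ids)})


def write_embedding_file(table: EmbeddingTable, path, sep: str = ",") -> None:
    """Inverse of :func:`load_embedding_file` (full float precision)."""
    ids = list(table.vectors)
    mat = np.vstack([table.vectors[i] for i in ids]) if ids else np.zeros((0, table.dim))
    df = pd.DataFrame(mat, columns=[f"e{k}" for k in range(table.dim)])
    df.insert(0, "id", ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
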