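"""Seeded synthetic knowledge graphs with planted indication structure.

The benchmark generator plants a latent-block model: drugs, diseases and
proteins each carry a latent class in ``{1..B}``; a drug-disease indication
appears with probability ``p_in`` when classes match and ``p_out`` otherwise,
optionally modulated by heavy-tailed per-node degree propensities.  Auxiliary
relations (drug-protein, disease-protein, protein-protein) are correlated
with the same classes so that the graph context is informative about missing
indications, and an uncorrelated drug-drug relation provides pure noise.
A stated fraction of the planted indications is designated as held-out ground
truth for recovery experiments; initial embeddings are emitted either as
noisy copies of the latent structure (informative) or as pure noise.

``primekg_miniature`` builds a schema mimic of the full biomedical graph
(10 node types, 30 relation labels) at toy scale for loader/filter tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import EmbeddingTable, attach_embeddings, write_embedding_file
from .graph import ConfigurationError, HeteroGraph, write_edge_table


class SpecificationError(ConfigurationError):
    """An infeasible or inconsistent generator specification."""


@dataclass
class SynthSpec:
    """Benchmark specification; defaults are the standard desk-scale instance."""

    n_drugs: int = 100
    n_diseases: int = 80
    n_proteins: int = 200
    n_blocks: int = 4
    p_in: float = 0.30
    p_out: float = 0.01
    heldout_fraction: float = 0.2
    degree_exponent: float | None = 2.5   # Pareto tail of propensities; None = uniform
    prob_cap: float = 0.95
    drug_protein: tuple = (0.20, 0.01)    # (within-class, background) densities
    disease_protein: tuple = (0.15, 0.01)
    protein_protein: tuple = (0.05, 0.005)
    drug_drug_noise: float = 0.01         # class-independent noise relation
    embedding_dim: int = 16
    embedding_noise: float = 0.5
    informative_embeddings: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        probs = [self.p_in, self.p_out, self.drug_drug_noise, *self.drug_protein,
                 *self.disease_protein, *self.protein_protein]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SpecificationError("all edge probabilities must lie in [0, 1]")
        if min(self.n_drugs, self.n_diseases, self.n_proteins, self.n_blocks) < 1:
            raise SpecificationError("node and block counts must be positive")
        if not 0.0 <= self.heldout_fraction < 1.0:
            raise SpecificationError("heldout_fraction must lie in [0, 1)")
        if self.embedding_dim < 1:
            raise SpecificationError("embedding_dim must be positive")


@dataclass
class SynthResult:
    graph: HeteroGraph                   # embedded; includes held-out edges
    heldout: set                         # designated validation ground truth
    tables: dict[str, EmbeddingTable]
    classes: dict[str, np.ndarray]       # per-type latent class labels
    target_prob_matrix: np.ndarray       # (n_drugs, n_diseases) planted probabilities
    spec: SynthSpec


def _propensities(n: int, exponent: float | None, rng) -> np.ndarray:
    if exponent is None:
        return np.ones(n)
    # Pareto with tail index `exponent`, rescaled to mean 1
    x = rng.pareto(exponent, size=n) + 1.0
    return x / x.mean()


def _block_bipartite(rng, cls_a, cls_b, p_in, p_out, prop_a=None, prop_b=None, cap=0.95):
    base = np.where(cls_a[:, None] == cls_b[None, :], p_in, p_out).astype(float)
    if prop_a is not None:
        base = base * prop_a[:, None] * prop_b[None, :]
    np.clip(base, 0.0, cap, out=base)
    edges = np.argwhere(rng.random(base.shape) < base)
    return base, edges


def generate(spec: SynthSpec) -> SynthResult:
    """Draw a benchmark instance; same spec + seed -> identical output."""
    rng = np.random.Generator(np.random.PCG64(spec.rng_seed))
    drugs = [f"d{i}" for i in range(spec.n_drugs)]
    diseases = [f"s{i}" for i in range(spec.n_diseases)]
    proteins = [f"p{i}" for i in range(spec.n_proteins)]
    B = spec.n_blocks
    cls = {
        "drug": rng.integers(0, B, size=spec.n_drugs),
        "disease": rng.integers(0, B, size=spec.n_diseases),
        "protein": rng.integers(0, B, size=spec.n_proteins),
    }
    prop_drug = _propensities(spec.n_drugs, spec.degree_exponent, rng)
    prop_dis = _propensities(spec.n_diseases, spec.degree_exponent, rng)

    pmat, target_edges = _block_bipartite(rng, cls["drug"], cls["disease"],
                                          spec.p_in, spec.p_out,
                                          prop_drug, prop_dis, spec.prob_cap)
    _, dp_edges = _block_bipartite(rng, cls["drug"], cls["protein"],
                                   *spec.drug_protein)
    _, sp_edges = _block_bipartite(rng, cls["disease"], cls["protein"],
                                   *spec.disease_protein)
    pp_base = np.where(cls["protein"][:, None] == cls["protein"][None, :],
                       spec.protein_protein[0], spec.protein_protein[1])
    upper = np.triu(rng.random(pp_base.shape) < pp_base, k=1)
    pp_edges = np.argwhere(upper)
    dd_edges = np.argwhere(np.triu(
        rng.random((spec.n_drugs, spec.n_drugs)) < spec.drug_drug_noise, k=1))

    def both_ways(e):  # same-type relations store both orientations
        return np.vstack([e, e[:, ::-1]]) if len(e) else np.zeros((0, 2), dtype=np.intp)

    edges = {
        ("drug", "indication", "disease"): target_edges,
        ("drug", "drug_protein", "protein"): dp_edges,
        ("disease", "disease_protein", "protein"): sp_edges,
        ("protein", "protein_protein", "protein"): both_ways(pp_edges),
        ("drug", "drug_drug", "drug"): both_ways(dd_edges),
    }
    g = HeteroGraph({"drug": drugs, "disease": diseases, "protein": proteins}, edges)

    pairs = [(drugs[i], diseases[j]) for i, j in target_edges]
    rng.shuffle(pairs)
    n_held = int(round(spec.heldout_fraction * len(pairs)))
    heldout = set(pairs[:n_held])

    tables = _make_embeddings(spec, rng, cls,
                              {"drug": prop_drug, "disease": prop_dis},
                              {"drug": drugs, "disease": diseases, "protein": proteins})
    g = attach_embeddings(g, tables, policy="strict")
    return SynthResult(graph=g, heldout=heldout, tables=tables, classes=cls,
                       target_prob_matrix=pmat, spec=spec)


def _make_embeddings(spec, rng, cls, props, ids_by_type) -> dict[str, EmbeddingTable]:
    B = spec.n_blocks
    tables = {}
    for t, ids in ids_by_type.items():
        n, dim = len(ids), spec.embedding_dim
        mat = rng.standard_normal((n, dim))
        if spec.informative_embeddings:
            signal = np.zeros((n, dim))
            onehot_width = min(B, dim)
            signal[np.arange(n), cls[t] % onehot_width] = 1.0
            if dim > B and t in props:
                signal[:, B] = props[t]
            mat = signal + spec.embedding_noise * rng.standard_normal((n, dim))
        tables[t] = EmbeddingTable(t, dim, {i: mat[k] for k, i in enumerate(ids)})
    return tables


def null_spec(base: SynthSpec | None = None) -> SynthSpec:
    """The no-signal control: class structure and degree signal both removed.

    With heavy-tailed propensities the per-pair link probability is
    predictable from degrees alone, so a fair "no signal" control must flatten
    the propensities as well as equalize the in/out densities.  The common
    density is the default instance's mean link rate, keeping edge counts
    comparable.
    """
    base = base or SynthSpec()
    p_mean = (base.p_in + (base.n_blocks - 1) * base.p_out) / base.n_blocks
    return SynthSpec(n_drugs=base.n_drugs, n_diseases=base.n_diseases,
                     n_proteins=base.n_proteins, n_blocks=base.n_blocks,
                     p_in=p_mean, p_out=p_mean, heldout_fraction=base.heldout_fraction,
                     degree_exponent=None, drug_protein=base.drug_protein,
                     disease_protein=base.disease_protein,
                     protein_protein=base.protein_protein,
                     drug_drug_noise=base.drug_drug_noise,
                     embedding_dim=base.embedding_dim,
                     embedding_noise=base.embedding_noise,
                     informative_embeddings=base.informative_embeddings,
                     rng_seed=base.rng_seed)


def write_dataset(result: SynthResult, out_dir) -> dict:
    """Write edge CSV + embedding files + held-out truth table for the CLI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_table(result.graph, out / "edges.csv")
    for t, table in result.tables.items():
        write_embedding_file(table, out / f"embeddings_{t}.csv")
    truth = pd.DataFrame(sorted(result.heldout), columns=["drug", "disease"])
    truth.to_csv(out / "heldout.csv", index=False)
    manifest = {"spec": asdict(result.spec), "files": {
        "edges": "edges.csv",
        "heldout": "heldout.csv",
        "embeddings": {t: f"embeddings_{t}.csv" for t in result.tables}}}
    (out / "dataset.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# -- PrimeKG schema miniature -----------------------------------------------

MINIATURE_NODE_TYPES = {
    "drug": 12, "disease": 10, "protein": 20, "phenotype": 8, "anatomy": 6,
    "biological_process": 8, "molecular_function": 6, "cellular_component": 5,
    "pathway": 5, "exposure": 4,
}

# the 30 relation labels of the full biomedical schema, with endpoint types
MINIATURE_RELATIONS = [
    ("anatomy", "anatomy_protein_present", "protein"),
    ("drug", "drug_drug", "drug"),
    ("protein", "protein_protein", "protein"),
    ("disease", "disease_phenotype_positive", "phenotype"),
    ("biological_process", "bioprocess_protein", "protein"),
    ("cellular_component", "cellcomp_protein", "protein"),
    ("disease", "disease_protein", "protein"),
    ("molecular_function", "molfunc_protein", "protein"),
    ("drug", "drug_phenotype", "phenotype"),
    ("biological_process", "bioprocess_bioprocess", "biological_process"),
    ("pathway", "pathway_protein", "protein"),
    ("disease", "disease_disease", "disease"),
    ("drug", "contraindication", "disease"),
    ("drug", "drug_protein", "protein"),
    ("anatomy", "anatomy_protein_absent", "protein"),
    ("phenotype", "phenotype_phenotype", "phenotype"),
    ("anatomy", "anatomy_anatomy", "anatomy"),
    ("molecular_function", "molfunc_molfunc", "molecular_function"),
    ("drug", "indication", "disease"),
    ("cellular_component", "cellcomp_cellcomp", "cellular_component"),
    ("phenotype", "phenotype_protein", "protein"),
    ("drug", "off_label_use", "disease"),
    ("pathway", "pathway_pathway", "pathway"),
    ("exposure", "exposure_disease", "disease"),
    ("exposure", "exposure_exposure", "exposure"),
    ("exposure", "exposure_bioprocess", "biological_process"),
    ("exposure", "exposure_protein", "protein"),
    ("disease", "disease_phenotype_negative", "phenotype"),
    ("exposure", "exposure_molfunc", "molecular_function"),
    ("exposure", "exposure_cellcomp", "cellular_component"),
]


def primekg_miniature(rng_seed: int = 0, edges_per_relation: int = 6,
                      indicated_drugs: int = 8, indicated_diseases: int = 7
                      ) -> tuple[HeteroGraph, dict]:
    """Schema mimic of the full biomedical graph at toy scale.

    Indication edges only touch the first ``indicated_drugs`` drugs and
    ``indicated_diseases`` diseases, so the expected outcome of
    indication-based node filtering is known by construction and returned in
    the metadata.
    """
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    nodes = {t: [f"{t}_{i}" for i in range(n)] for t, n in MINIATURE_NODE_TYPES.items()}
    edges = {}
    for st, rel, tt in MINIATURE_RELATIONS:
        ns, nt = MINIATURE_NODE_TYPES[st], MINIATURE_NODE_TYPES[tt]
        if rel == "indication":
            pool = [(i, j) for i in range(indicated_drugs) for j in range(indicated_diseases)]
        else:
            pool = [(i, j) for i in range(ns) for j in range(nt)
                    if not (st == tt and i == j)]
        k = min(edges_per_relation, len(pool))
        chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        edges[(st, rel, tt)] = np.asarray(chosen, dtype=np.intp)
    g = HeteroGraph(nodes, edges)
    ind = edges[("drug", "indication", "disease")]
    meta = {
        "indicated_drug_ids": sorted({nodes["drug"][i] for i, _ in ind}),
        "indicated_disease_ids": sorted({nodes["disease"][j] for _, j in ind}),
        "relation_labels": sorted({r for _, r, _ in MINIATURE_RELATIONS}),
    }
    return g, meta
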