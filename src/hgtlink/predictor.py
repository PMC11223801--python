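"""Pair scoring, negative sampling, loss and the end-to-end training loop.

The decoder is a two-layer fully connected network on the concatenated
encoder features of a (drug, disease) pair:

    score = sigmoid( W2 . dropout( ReLU( BatchNorm( W1 [f_drug ; f_disease] ))) )

with dropout 0.2 after the first layer.  Training masks a fraction of target
edges out of the graph, samples type-budgeted subgraphs from seed drugs, and
minimizes binary cross-entropy over each batch's usable masked positives plus
an equal number of fresh uniform negatives (pairs of the subgraph's drugs and
diseases that are not known positives).  Encoder and decoder parameters are
updated jointly by AdamW under a cosine-annealed learning rate.

Defaults echo the published setup: 300 epochs, AdamW, cosine annealing,
sampling batches of 164 seed drugs, 512-node per-type budgets.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import seeding
from .autodiff import AdamW, BatchNorm1d, CosineAnnealingLR, Linear, Module, Tensor, \
    concat, dropout, gather, log, relu, sigmoid
from .encoder import EncoderConfig, HGTEncoder
from .graph import ConfigurationError, HeteroGraph, IndicationSplit
from .sampler import SamplerConfig, partition_seeds, sample_subgraph


class PoolExhaustedError(ConfigurationError):
    """Fewer admissible negative pairs exist than were requested."""


@dataclass
class DecoderConfig:
    dropout_p: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ConfigurationError("dropout probability must lie in [0, 1]")


@dataclass
class TrainConfig:
    epochs: int = 300
    optimizer: str = "adamw"
    lr: float = 1e-3
    weight_decay: float = 1e-2
    betas: tuple = (0.9, 0.999)
    lr_schedule: str = "cosine"
    lr_min: float = 0.0
    mask_fraction: float = 0.8
    negatives_per_positive: float = 1.0
    rng_seed: int = 0
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.negatives_per_positive <= 0:
            raise ConfigurationError("negatives_per_positive must be positive")
        if self.optimizer != "adamw":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ConfigurationError(f"unsupported schedule {self.lr_schedule!r}")


@dataclass
class ScoredPair:
    drug: object
    disease: object
    score: float
    label: int


class PairScorer(Module):
    """Two-layer FC decoder with batch normalization; scores in (0, 1)."""

    def __init__(self, d_model: int, cfg: DecoderConfig, rng: np.random.Generator):
        self.d_model = d_model
        self.cfg = cfg
        self.lin1 = Linear(2 * d_model, d_model, rng)
        self.bn = BatchNorm1d(d_model)
        self.lin2 = Linear(d_model, 1, rng)

    def logits(self, feat_a: Tensor, feat_b: Tensor, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        x = concat([feat_a, feat_b], axis=1)
        x = relu(self.bn(self.lin1(x), train=train))
        if train:
            if rng is None:
                raise ConfigurationError("train-mode scoring needs an rng for dropout")
            x = dropout(x, self.cfg.dropout_p, rng, train=True)
        return self.lin2(x).reshape(-1)

    def __call__(self, feat_a: Tensor, feat_b: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        return sigmoid(self.logits(feat_a, feat_b, train, rng))


def score_pairs(feat: dict[str, np.ndarray], pairs: list[tuple], scorer: PairScorer,
                index: dict[str, dict], types: tuple[str, str],
                train: bool = False, rng: np.random.Generator | None = None,
                labels: dict | None = None) -> list[ScoredPair]:
    """Score (a, b) id pairs given per-type feature matrices and id indices."""
    ta, tb = types
    rows_a, rows_b = [], []
    for a, b in pairs:
        if a not in index.get(ta, {}) or b not in index.get(tb, {}):
            raise KeyError(f"pair ({a!r}, {b!r}) has an endpoint without features")
        rows_a.append(index[ta][a])
        rows_b.append(index[tb][b])
    fa = gather(_as_tensor(feat[ta]), np.asarray(rows_a, dtype=np.intp))
    fb = gather(_as_tensor(feat[tb]), np.asarray(rows_b, dtype=np.intp))
    s = scorer(fa, fb, train=train, rng=rng)
    labels = labels or {}
    return [ScoredPair(a, b, float(v), int(labels.get((a, b), 1)))
            for (a, b), v in zip(pairs, s.data)]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def sample_negatives(drugs: list, diseases: list, n_neg: int, forbidden: set,
                     rng: np.random.Generator, self_paired: bool = False) -> list[tuple]:
    """Draw ``n_neg`` distinct pairs uniformly from drugs x diseases minus
    ``forbidden`` (checked in both orientations).  For self-paired relations
    the pool is unordered pairs without self-pairs."""
    if not drugs or not diseases:
        raise PoolExhaustedError("need at least one node on each side")
    if self_paired:
        ids = sorted(set(drugs) | set(diseases), key=repr)
        pool = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        pool = [p for p in pool if p not in forbidden and (p[1], p[0]) not in forbidden]
    else:
        pool = [(a, b) for a in drugs for b in diseases
                if (a, b) not in forbidden and (b, a) not in forbidden]
    if len(pool) < n_neg:
        raise PoolExhaustedError(
            f"requested {n_neg} negatives but only {len(pool)} admissible pairs exist")
    pool.sort(key=repr)
    chosen = rng.choice(len(pool), size=n_neg, replace=False)
    return [pool[i] for i in chosen]


def bce_loss(scored: list[ScoredPair]) -> float:
    """Mean binary cross-entropy of a scored-pair list."""
    if not scored:
        raise ConfigurationError("bce_loss of an empty list is undefined")
    y = np.array([p.label for p in scored], dtype=float)
    s = np.clip(np.array([p.score for p in scored], dtype=float), 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


def _bce_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Numerically stable BCE on logits (identical value to probability form)."""
    y = Tensor(np.asarray(labels, dtype=float))
    p = sigmoid(logits)
    eps = 1e-12
    return -(y * log(p + eps) + (1.0 - y) * log(1.0 - p + eps)).mean()


class RepurposingModel(Module):
    """Encoder + decoder bundle with checkpointing."""

    def __init__(self, encoder: HGTEncoder, scorer: PairScorer):
        self.encoder = encoder
        self.scorer = scorer

    @classmethod
    def for_graph(cls, g: HeteroGraph, enc_cfg: EncoderConfig, dec_cfg: DecoderConfig,
                  rng: np.random.Generator) -> "RepurposingModel":
        enc = HGTEncoder.for_graph(g, enc_cfg, rng)
        return cls(enc, PairScorer(enc_cfg.d_model, dec_cfg, rng))

    def save(self, path) -> None:
        state = self.named_parameters()
        header = {
            "encoder": asdict(self.encoder.cfg),
            "decoder": asdict(self.scorer.cfg),
            "input_dims": self.encoder.input_dims,
            "triples": self.encoder.triples,
        }
        arrays = {k.replace("/", "_"): v.data for k, v in state}
        arrays["__bn_running_mean"] = self.scorer.bn.running_mean
        arrays["__bn_running_var"] = self.scorer.bn.running_var
        arrays["__config_json"] = np.frombuffer(
            json.dumps(header).encode("utf8"), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "RepurposingModel":
        with np.load(path) as z:
            header = json.loads(bytes(z["__config_json"]).decode("utf8"))
            enc_cfg = EncoderConfig(**header["encoder"])
            dec_cfg = DecoderConfig(**header["decoder"])
            rng = np.random.Generator(np.random.PCG64(0))
            enc = HGTEncoder(enc_cfg, header["input_dims"],
                             [tuple(t) for t in header["triples"]], rng)
            model = cls(enc, PairScorer(enc_cfg.d_model, dec_cfg, rng))
            state = {k: z[k] for k in z.files if not k.startswith("__")}
            model.load_state_dict(state)
            model.scorer.bn.running_mean = z["__bn_running_mean"].copy()
            model.scorer.bn.running_var = z["__bn_running_var"].copy()
        return model


@dataclass
class TrainResult:
    model: RepurposingModel
    history: list[dict]
    skipped_batches: int = 0
    audit: list[dict] | None = None


def train(g: HeteroGraph, split: IndicationSplit, enc_cfg: EncoderConfig,
          dec_cfg: DecoderConfig, cfg: TrainConfig,
          model: RepurposingModel | None = None, audit: bool = False,
          progress=None) -> TrainResult:
    """End-to-end masked-edge training on an embedded graph.

    ``g`` must already carry initial embeddings; the masked and validation
    pairs of ``split`` are removed from the view the sampler and encoder see.
    Per epoch, seed nodes are re-partitioned, one type-budgeted subgraph is
    sampled per batch, the usable masked positives (both endpoints inside the
    subgraph) are scored against an equal number of fresh negatives, and all
    parameters are updated jointly.  Fully reproducible from ``cfg.rng_seed``.
    """
    drug_type, disease_type = split.endpoint_types
    self_paired = drug_type == disease_type
    visible = split.apply(g)
    if visible.relation_pairs(split.target_relation) & (split.masked | split.validation):
        raise ConfigurationError("masked/validation pairs must be absent from the graph view")
    init_rng = seeding.stream(cfg.rng_seed, "init")
    if model is None:
        model = RepurposingModel.for_graph(visible, enc_cfg, dec_cfg, init_rng)
    drop_rng = seeding.stream(cfg.rng_seed, "dropout")
    neg_rng = seeding.stream(cfg.rng_seed, "negatives")
    samp_rng = seeding.stream(cfg.rng_seed, "sampler")
    opt = AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    sched = CosineAnnealingLR(opt, t_max=cfg.epochs, lr_min=cfg.lr_min) \
        if cfg.lr_schedule == "cosine" else None
    forbidden = split.positives
    history: list[dict] = []
    audits: list[dict] = [] if audit else None
    skipped = 0
    target_triples = set(visible.triples_for(split.target_relation))
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        batches = partition_seeds(visible.nodes[drug_type], cfg.sampler.seed_batch_size,
                                  seeding.spawn_seed(cfg.rng_seed, "partition", str(epoch)))
        losses = []
        for seeds in batches:
            batch = sample_subgraph(visible, seeds, cfg.sampler, samp_rng,
                                    seed_type=drug_type)
            # sorted so results do not depend on set iteration order
            positives = sorted((p for p in split.masked
                                if batch.contains_pair(p, split.endpoint_types)),
                               key=repr)
            if not positives:
                skipped += 1
                continue
            n_neg = max(1, int(round(cfg.negatives_per_positive * len(positives))))
            negatives = sample_negatives(batch.global_ids(drug_type),
                                         batch.global_ids(disease_type),
                                         n_neg, forbidden, neg_rng,
                                         self_paired=self_paired)
            if audit:
                sub_edges = set()
                for tr in target_triples:
                    if tr in batch.subgraph.edges:
                        sub_edges |= set(batch.subgraph.edge_ids(tr))
                audits.append({"epoch": epoch, "subgraph_target_edges": sub_edges,
                               "positives": list(positives), "negatives": list(negatives)})
            feat = model.encoder.encode(batch.subgraph, train=True, rng=drop_rng)
            pairs = positives + negatives
            labels = np.array([1] * len(positives) + [0] * len(negatives), dtype=float)
            rows_a = np.array([batch.local_index[drug_type][a] for a, _ in pairs])
            rows_b = np.array([batch.local_index[disease_type][b] for _, b in pairs])
            fa = gather(feat[drug_type], rows_a)
            fb = gather(feat[disease_type], rows_b)
            logits = model.scorer.logits(fa, fb, train=True, rng=drop_rng)
            loss = _bce_from_logits(logits, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append({"epoch": epoch, "loss": float(np.mean(losses)) if losses else np.nan,
                        "lr": opt.lr, "batches": len(losses),
                        "seconds": time.perf_counter() - t0})
        if sched is not None:
            sched.step()
        if progress is not None:
            progress(history[-1])
    return TrainResult(model=model, history=history, skipped_batches=skipped, audit=audits)


def score_pairs_batched(model: RepurposingModel, visible: HeteroGraph, pairs: list[tuple],
                        types: tuple[str, str], sampler_cfg: SamplerConfig,
                        rng: np.random.Generator, n_sets: int = 1,
                        collect_batches: list | None = None) -> dict[tuple, float]:
    """Eval-mode scores for id pairs, via subgraphs covering all seed nodes.

    Runs ``n_sets`` passes over the seed-type nodes; a pair is scored in every
    batch containing both endpoints and its scores are averaged.  Pairs never
    covered are absent from the result.
    """
    drug_type, disease_type = types
    sums: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    for s in range(n_sets):
        seed_batches = partition_seeds(visible.nodes[drug_type], sampler_cfg.seed_batch_size,
                                       int(rng.integers(0, 2**31 - 1)))
        for seeds in seed_batches:
            batch = sample_subgraph(visible, seeds, sampler_cfg, rng, seed_type=drug_type)
            if collect_batches is not None:
                collect_batches.append(batch)
            covered = [p for p in pairs if batch.contains_pair(p, types)]
            if not covered:
                continue
            feat = model.encoder.encode(batch.subgraph, train=False)
            scored = score_pairs({t: f for t, f in feat.items()}, covered, model.scorer,
                                 batch.local_index, types, train=False)
            for sp in scored:
                key = (sp.drug, sp.disease)
                sums[key] = sums.get(key, 0.0) + sp.score
                counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}
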