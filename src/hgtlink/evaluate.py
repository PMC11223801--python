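"""Evaluation protocols for knowledge-graph link prediction.

AUROC (rank / Mann-Whitney formulation, ties at half weight) and AUPR
(step-wise precision-recall area) are the two metrics.  On top of them sit
the study protocols: k-fold cross-validation over target pairs, novel-pair
ranking from a model trained with every target edge present, relation
retargeting (the identical pipeline pointed at another relation type),
relation-removal robustness sweeps, and a new-disease scenario in which
held-out diseases keep a single training indication and lose their
text-derived embeddings.

Within a fold, scored pairs are pooled across sampled batches before the
metrics are computed; the headline number is the arithmetic mean over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import seeding
from .embeddings import random_embeddings
from .encoder import EncoderConfig
from .graph import (ConfigurationError, HeteroGraph, IndicationSplit, make_folds,
                    remove_relation, split_indications)
from .predictor import (DecoderConfig, RepurposingModel, ScoredPair, TrainConfig,
                        sample_negatives, score_pairs_batched, train)


class UndefinedMetricError(ConfigurationError):
    """Metric undefined for single-class input."""


def _split_labels_scores(scored) -> tuple[np.ndarray, np.ndarray]:
    if scored and isinstance(scored[0], ScoredPair):
        y = np.array([p.label for p in scored])
        s = np.array([p.score for p in scored])
    else:
        y, s = np.asarray(scored[0]), np.asarray(scored[1])
    return y.astype(int), s.astype(float)


def auroc(*scored) -> float:
    """P(random positive outranks random negative), ties counted half."""
    y, s = _split_labels_scores(scored if len(scored) > 1 else scored[0])
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(y, s))


def aupr(*scored) -> float:
    """Area under precision-recall via step-wise interpolation."""
    y, s = _split_labels_scores(scored if len(scored) > 1 else scored[0])
    if y.sum() == 0:
        raise UndefinedMetricError("AUPR needs at least one positive")
    return float(average_precision_score(y, s))


@dataclass
class MetricReport:
    auroc_per_fold: list[float]
    aupr_per_fold: list[float]
    missing_folds: list[int] = field(default_factory=list)
    condition: str = ""

    @property
    def auroc(self) -> float:
        return float(np.mean(self.auroc_per_fold))

    @property
    def aupr(self) -> float:
        return float(np.mean(self.aupr_per_fold))


@dataclass
class PipelineConfig:
    """Everything one experiment needs, bar the graph itself."""

    target_relation: str = "indication"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    eval_sets: int = 1


def retarget(cfg: PipelineConfig, new_target_relation: str,
             g: HeteroGraph | None = None) -> PipelineConfig:
    """The identical pipeline pointed at another relation type.

    Endpoint types are inferred from the graph schema at run time; splits,
    negatives and scoring are all defined over the new endpoint-type pair.
    Self-paired relations use unordered pair semantics without self-pairs.
    """
    if g is not None:
        g.endpoint_types(new_target_relation)  # raises if absent/ambiguous
    return replace(cfg, target_relation=new_target_relation)


def _evaluate_fold(model: RepurposingModel, visible: HeteroGraph,
                   split: IndicationSplit, cfg: PipelineConfig,
                   seed: int, tag: str) -> tuple[float, float] | None:
    """Pooled AUROC/AUPR of validation positives vs. an equal count of fresh
    negatives, scored through sampled subgraphs covering all seed nodes."""
    types = split.endpoint_types
    neg_rng = seeding.stream(seed, "eval-negatives", tag)
    try:
        negatives = sample_negatives(visible.nodes[types[0]], visible.nodes[types[1]],
                                     len(split.validation), split.positives, neg_rng,
                                     self_paired=types[0] == types[1])
    except ConfigurationError:
        return None
    pairs = sorted(split.validation, key=repr) + negatives
    labels = {p: 1 for p in split.validation}
    labels.update({p: 0 for p in negatives})
    samp_rng = seeding.stream(seed, "eval-sampler", tag)
    scores = score_pairs_batched(model, visible, pairs, types, cfg.training.sampler,
                                 samp_rng, n_sets=cfg.eval_sets)
    y = np.array([labels[p] for p in scores])
    s = np.array([scores[p] for p in scores])
    if len(np.unique(y)) < 2:
        return None
    return auroc(y, s), aupr(y, s)


def cross_validate(g: HeteroGraph, cfg: PipelineConfig, k: int = 5,
                   rng_seed: int = 0, progress=None) -> MetricReport:
    """k-fold cross-validation over target-relation pairs.

    Per fold, the fold's pairs are removed from the graph entirely, the rest
    are split masked/unmasked by ``mask_fraction``, a fresh model is trained,
    and the fold's pairs plus an equal number of fresh negatives are scored.
    """
    if k < 2:
        raise ConfigurationError("cross-validation needs k >= 2")
    pairs = g.relation_pairs(cfg.target_relation)
    folds = make_folds(pairs, k, seeding.spawn_seed(rng_seed, "folds"))
    auc_list, pr_list, missing = [], [], []
    for i in range(k):
        split = split_indications(g, cfg.target_relation, cfg.training.mask_fraction,
                                  seeding.spawn_seed(rng_seed, "split", str(i)),
                                  validation=folds.fold(i))
        tc = replace(cfg.training, rng_seed=seeding.spawn_seed(rng_seed, "train", str(i)))
        result = train(g, split, cfg.encoder, cfg.decoder, tc)
        visible = split.apply(g)
        metrics = _evaluate_fold(result.model, visible, split, cfg, rng_seed, f"fold{i}")
        if metrics is None:
            missing.append(i)
            continue
        auc_list.append(metrics[0])
        pr_list.append(metrics[1])
        if progress is not None:
            progress({"fold": i, "auroc": metrics[0], "aupr": metrics[1]})
    if not auc_list:
        raise ConfigurationError("no fold produced a defined metric")
    return MetricReport(auc_list, pr_list, missing_folds=missing)


def holdout_evaluate(g: HeteroGraph, heldout: set, cfg: PipelineConfig,
                     rng_seed: int = 0) -> tuple[MetricReport, "TrainOutput"]:
    """Train once with ``heldout`` pairs as validation; report their recovery.

    This is the single-split analogue of one cross-validation fold, used for
    benchmarks where the generator itself supplies the held-out ground truth.
    """
    split = split_indications(g, cfg.target_relation, cfg.training.mask_fraction,
                              seeding.spawn_seed(rng_seed, "split"), validation=heldout)
    tc = replace(cfg.training, rng_seed=seeding.spawn_seed(rng_seed, "train"))
    result = train(g, split, cfg.encoder, cfg.decoder, tc)
    visible = split.apply(g)
    metrics = _evaluate_fold(result.model, visible, split, cfg, rng_seed, "holdout")
    if metrics is None:
        raise ConfigurationError("held-out evaluation produced no defined metric")
    report = MetricReport([metrics[0]], [metrics[1]])
    return report, TrainOutput(result=result, split=split, visible=visible)


@dataclass
class TrainOutput:
    result: object
    split: IndicationSplit
    visible: HeteroGraph


def rank_novel(g: HeteroGraph, model: RepurposingModel, cfg: PipelineConfig,
               n_sets: int = 10, rng_seed: int = 0) -> list[ScoredPair]:
    """Rank candidate pairs of the target relation, excluding known positives.

    The model must have been trained with all target pairs present in the
    graph; ``n_sets`` full passes over the seed nodes are sampled and every
    drug-disease pair co-occurring in a subgraph is scored (averaged over
    batches), then sorted by descending score.
    """
    types = g.endpoint_types(cfg.target_relation)
    known = g.relation_pairs(cfg.target_relation)
    if types[0] == types[1]:
        ids = g.nodes[types[0]]
        candidates = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    else:
        candidates = [(a, b) for a in g.nodes[types[0]] for b in g.nodes[types[1]]]
    candidates = [p for p in candidates if p not in known and (p[1], p[0]) not in known]
    rng = seeding.stream(rng_seed, "novel-sampler")
    scores = score_pairs_batched(model, g, candidates, types, cfg.training.sampler,
                                 rng, n_sets=n_sets)
    ranked = [ScoredPair(a, b, s, 0) for (a, b), s in scores.items()]
    ranked.sort(key=lambda p: (-p.score, repr((p.drug, p.disease))))
    return ranked


def robustness_sweep(g: HeteroGraph, relations_to_drop: list[str], cfg: PipelineConfig,
                     k: int = 5, rng_seed: int = 0) -> list[MetricReport]:
    """Cross-validate once per dropped relation plus a no-drop baseline."""
    reports = []
    baseline = cross_validate(g, cfg, k=k, rng_seed=rng_seed)
    baseline.condition = "nothing removed"
    reports.append(baseline)
    for rel in relations_to_drop:
        if rel == cfg.target_relation:
            raise ConfigurationError("cannot drop the target relation itself")
        r = cross_validate(remove_relation(g, rel), cfg, k=k, rng_seed=rng_seed)
        r.condition = f"removed {rel}"
        reports.append(r)
    return reports


def new_disease_scenario(g: HeteroGraph, cfg: PipelineConfig, test_fraction: float = 0.1,
                         rng_seed: int = 0, fallback_dim: int | None = None
                         ) -> tuple[MetricReport, dict]:
    """Disease-level holdout with text embeddings replaced by random vectors.

    A ``test_fraction`` share of diseases is held out; each held-out disease
    keeps exactly one indication in the training data (diseases with fewer
    than two indications are excluded from scoring and logged).  Disease
    embeddings are replaced by the seeded fallback initializer, emulating
    entities for which no literature-derived vector exists.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError("test_fraction must lie strictly between 0 and 1")
    drug_type, disease_type = g.endpoint_types(cfg.target_relation)
    pairs = g.relation_pairs(cfg.target_relation)
    by_disease: dict = {}
    for a, b in pairs:
        by_disease.setdefault(b, []).append((a, b))
    rng = seeding.stream(rng_seed, "new-disease")
    diseases = sorted(by_disease, key=repr)
    rng.shuffle(diseases)
    n_test = int(np.floor(test_fraction * g.num_nodes(disease_type)))
    held_diseases = diseases[:n_test]
    excluded = [d for d in held_diseases if len(by_disease[d]) < 2]
    held_diseases = [d for d in held_diseases if len(by_disease[d]) >= 2]
    retained, validation = set(), set()
    for d in held_diseases:
        inds = sorted(by_disease[d], key=repr)
        keep = inds[int(rng.integers(len(inds)))]
        retained.add(keep)
        validation.update(p for p in inds if p != keep)
    # swap the disease embeddings for the seeded fallback
    dim = fallback_dim or g.embeddings[disease_type].shape[1]
    fallback = random_embeddings(g, {disease_type: dim},
                                 seeding.spawn_seed(rng_seed, "fallback"))[disease_type]
    emb = dict(g.embeddings)
    emb[disease_type] = np.vstack([fallback.vectors[i] for i in g.nodes[disease_type]])
    g2 = g.with_embeddings(emb)
    split = split_indications(g2, cfg.target_relation, cfg.training.mask_fraction,
                              seeding.spawn_seed(rng_seed, "split"), validation=validation)
    # the retained one-per-disease indications must stay visible in the graph
    split.masked -= retained
    split.unmasked |= retained
    tc = replace(cfg.training, rng_seed=seeding.spawn_seed(rng_seed, "train"))
    result = train(g2, split, cfg.encoder, cfg.decoder, tc)
    visible = split.apply(g2)
    metrics = _evaluate_fold(result.model, visible, split, cfg, rng_seed, "newdisease")
    if metrics is None:
        raise ConfigurationError("new-disease evaluation produced no defined metric")
    info = {"held_out_diseases": held_diseases, "excluded_diseases": excluded,
            "retained": retained, "validation": validation, "split": split,
            "result": result}
    return MetricReport([metrics[0]], [metrics[1]]), info
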