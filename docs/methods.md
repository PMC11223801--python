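# Methods

## Problem setting

Given a heterogeneous knowledge graph `G = (V, E, A, R)` with type maps
`τ: V → A` and `φ: E → R`, the set of drug–disease indications
`I = {(Dr_i, Di_i)}` is split into a portion that remains in the graph
(`I_input`, the unmasked edges), a portion hidden from the graph and used as
training positives (`I_pos`, the masked edges), and — under cross-validation
— a held-out validation fold.  Negatives `I_neg` are drug×disease pairs that
are not known indications.  The model scores pairs in (0, 1); predicting the
hidden links from graph context simulates repurposing, and at deployment the
model is trained with every known indication present and asked to rank the
unknown pairs.

Indication pairs are treated as unordered: masking a pair removes every
stored orientation.  Edges are stored directed; for message passing a reverse
relation (`rev__<name>`) is materialized for any relation not already stored
in both orientations, so information flows both ways while the encoder only
ever aggregates from sources into targets.

## Encoder

Per layer, per head `i`, per edge `e = (s, t)`:

* attention score `(K_i(s) W_att^{φ(e)} Q_i(t)ᵀ) · μ⟨τ(s),φ(e),τ(t)⟩ / √d_head`,
  with `K_i, Q_i` node-type-specific projections, `W_att` a per-relation
  `d_head × d_head` map, and `μ` a learnable scalar per meta-relation
  (initialized at 1 so no relation is favored a priori);
* message `M_i(s) W_msg^{φ(e)}`;
* softmax over all in-neighbors of `t` (per head, across relations, with
  max-subtraction for numerical stability), weighted message sum, per-type
  output projection `A_linear`, activation and residual.

Choices made where the formulation leaves room:

* the attention denominator `√d` uses `d_head = d_model / h`, the standard
  multi-head scaling;
* the activation after `A_linear` is GELU (config-switchable to ReLU);
  GELU(0) = 0, so isolated nodes with a zero-bias output projection reduce to
  a pure residual pass-through;
* all projections carry biases, initialized fan-in-scaled uniform from a
  seeded generator;
* the input projection (ReLU, then dropout 0.5 in train mode) maps per-type
  input embeddings — which may have different dimensions per type — to
  `d_model`, guaranteeing the residual width from layer 1 on;
* the outputs of all `L` layers are concatenated (width `L·d_model`) and
  mapped back to `d_model` by a shared linear + ReLU head (a per-type head is
  available behind a flag);
* no dropout is applied between HGT layers (only the input projection's);
* meta-relations unseen at construction are instantiated on the fly in train
  mode and are an error in eval mode.

Defaults: `L = 3`, `h = 8`, `d_model = 64`, input dropout 0.5.

## Subgraph sampling

Mini-batches are built from seed drugs.  Every sampled node deposits
normalized-degree importance (1 / within-relation out-degree) on its
neighbors over the reverse-augmented edge set; each of `depth` iterations
draws up to `budget_per_type` new nodes per type with probability
proportional to squared accumulated importance, all types drawing from the
iteration-start budget so one iteration advances the frontier by exactly one
hop.  The batch is the induced subgraph on everything sampled.  Seeds are
free (they do not count against the first iteration's budget).  Masked and
validation edges are absent from the graph view the sampler sees, so hidden
links cannot leak into any batch — the test suite audits this exhaustively.

Defaults: depth 3 (one hop per encoder layer), budget 512, seed batches
of 164.

## Decoder, loss and optimization

`Score = σ(W₂ · Dropout₀.₂(ReLU(BatchNorm(W₁ [Feat_drug ; Feat_disease]))))`.
Batch-norm running statistics (momentum 0.1, unbiased variance) are frozen at
evaluation.  The loss is mean binary cross-entropy per batch over that
batch's usable masked positives plus an equal count of freshly resampled
uniform negatives (negatives are redrawn every epoch; the 1:1 ratio is
configurable).  Training uses AdamW (defaults lr 1e-3, weight decay 1e-2,
betas 0.9/0.999) with cosine annealing over the full epoch count to a minimum
learning rate of 0, 300 epochs by default.  For numerical stability the
training loss is computed from logits; it equals the probability-space
cross-entropy exactly.

Randomness is organized as named streams fanned out from one run seed
(splitting, sampling, negatives, dropout, initialization), so identical seeds
reproduce runs bit-for-bit on the same hardware, and all set-valued
intermediates are iterated in a canonical order so results do not depend on
the process hash seed.

## Evaluation protocols

AUROC uses the rank (Mann–Whitney) formulation with ties at half weight;
AUPR is the step-wise precision–recall area.  Within a fold, scored pairs
are pooled across sampled batches before computing metrics; headline numbers
are means over folds.  Validation scoring runs through sampled subgraphs
covering all seed drugs (the same machinery as training); a pair scored in
several batches gets the mean score.

* **Cross-validation** (k = 5): the fold's pairs are removed from the graph
  entirely, the remaining pairs are masked at `mask_fraction` (interpreted
  over the training portion), a fresh model is trained, and the fold's pairs
  plus an equal number of fresh negatives are scored.
* **Novel ranking**: trained with all indications present, the model scores
  every unknown pair co-occurring in sampled subgraphs over `n_sets` passes,
  sorted descending.
* **Retargeting**: the identical pipeline pointed at another relation;
  endpoint types are inferred from the schema, self-paired relations use
  unordered semantics without self-pairs.
* **Robustness**: cross-validation repeated with one relation type removed,
  plus a no-drop baseline; removing a zero-edge relation reproduces the
  baseline bit-for-bit under identical seeds.
* **New-disease scenario**: a fraction of diseases is held out, their
  text-derived embeddings are replaced by the seeded random fallback, and
  exactly one indication per held-out disease stays visible in the training
  graph; diseases with fewer than two indications are excluded from scoring.

## Synthetic benchmark

The generator plants a latent-block model.  Drugs, diseases and proteins
carry classes in `{1..B}`; an indication appears with probability `p_in`
(classes match) or `p_out` (otherwise), multiplied by per-node degree
propensities drawn from a Pareto(2.5) tail rescaled to mean 1 (pair
probabilities capped at 0.95) to emulate heavy-tailed degrees.  Drug–protein
(0.20/0.01), disease–protein (0.15/0.01) and protein–protein (0.05/0.005)
relations are correlated with the same classes, so graph context is
informative about missing indications; a drug–drug relation (density 0.01)
is pure noise, giving the robustness sweep a relation whose removal should
not matter.  Embeddings are emitted as the latent structure (class one-hot
plus propensity) plus N(0, 0.5²) noise in 16 dimensions, or as pure noise
for ablations.  A fifth of the planted indications is designated held-out
ground truth.  Everything is reproducible from the spec seed.

The default instance — 100 drugs, 80 diseases, 200 proteins, B = 4,
`p_in = 0.30`, `p_out = 0.01` — is the benchmark all desk-scale experiments
use.  What the generator does **not** emulate: real vocabulary identifiers,
biological semantics of relations, the empirical degree distributions of
public knowledge graphs, or correlated noise in text embeddings.  Passing
the recovery tests therefore shows the pipeline extracts planted relational
and feature signal at small scale; it does not certify performance on a real
release.

**Reduced benchmark model.**  2 layers, width 16, 4 heads, 200 epochs,
depth-3 sampling with 128-node budgets over 50-drug seed batches.  Input
dropout is halved to 0.25 and weight decay reduced to 1e-3, with lr 5e-3:
the desk-scale model is four times narrower and sees roughly forty times
fewer positives per epoch than the full-scale configuration, and the
full-scale regularization underfits it within the 200-epoch budget.

**Recovery measurement.**  Held-out AUROC is reported under the 1:1
negative protocol (the same protocol as cross-validation).  AUPR is reported
against the *full candidate pool* (every unknown drug×disease pair), where
the random-ranker baseline equals the positive prevalence (~0.017), so an
AUPR lift well above 1 is meaningful.  Note a small artifact of pool
ranking: excluding known positives removes proportionally more pairs of
high-degree drugs from the negative side, which slightly inflates pool AUROC
for degree-aware models; the 1:1 protocol is used for all threshold
comparisons.

**No-signal control.**  Setting `p_in = p_out` removes the class signal, but
heavy-tailed propensities alone make the per-pair link probability
predictable from degrees, so the control also flattens the propensities
(`degree_exponent = None`), with the common density chosen to preserve the
expected edge count.  Under iid flat edges the random masking split carries
no residual signal (a node's visible edge count is uninformative about its
remaining pairs), so any method should sit near AUROC 0.5.  Two caveats:
a single control instance has only ~130 held-out positives (AUROC standard
error ≈ 0.06), so the control statistic is the mean over three independent
instances; and the prescribed negative protocol itself — negatives are drawn
only from pairs that are not known positives — slightly under-represents
high-degree nodes on the negative side, which a node-memorizing model can
exploit for roughly +0.03 AUROC even with no generative signal.  The
measured control sits around 0.53.

## Known limitations

* No identifier mapping between vocabularies; inputs must share one
  namespace per node type (namespaced as `(type, id)`).
* No similarity-matrix construction — deliberately: all signal flows through
  typed relations and node features.
* Edge attributes are not supported; information attached to an edge (e.g.
  expression of a gene in a disease) cannot be used.
* The numpy engine is single-threaded and CPU-bound; it is intended for
  desk-scale graphs (tens of thousands of edges), not public releases with
  millions of edges.
* Whether a directed edge-count table for a symmetric relation lists one or
  both orientations is dataset-dependent; `relation_pairs` always reports
  unordered pair counts, and same-type relations generated here store both
  orientations.
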