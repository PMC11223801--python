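# hgtlink

Knowledge-graph link prediction for drug repurposing with a heterogeneous
graph transformer.

Drug repurposing asks which approved drugs might treat diseases they were
never indicated for.  `hgtlink` frames this as link prediction on a
heterogeneous biomedical knowledge graph `G = (V, E, A, R)`: nodes are typed
entities (drugs, diseases, proteins, phenotypes, ...), edges are typed
relations, and the target relation is the drug–disease *indication*.  A
fraction of the indication edges is masked out of the graph; the model learns
to predict the hidden links from graph context — a training-time simulation
of repurposing.

The package is aimed at computational drug-repurposing researchers who want a
self-contained, CPU-scale, fully seeded implementation of this pipeline:
typed graph construction and filtering, the encoder, budgeted subgraph
sampling, the scoring decoder, masked-edge training and the evaluation
protocols, plus a synthetic benchmark generator with planted ground truth.

## The model

**Encoder.**  Each layer of the heterogeneous graph transformer (HGT) updates
a target node `t` from its in-neighbors `s ∈ N(t)`.  Per attention head `i`
and edge `e = (s, t)` with meta-relation `⟨τ(s), φ(e), τ(t)⟩`:

    att_i(s,e,t) ∝ exp( K_i(s) · W_att^φ(e) · Q_i(t)ᵀ · μ⟨τ(s),φ(e),τ(t)⟩ / √d_head )
    msg_i(s,e,t) = M_i(s) · W_msg^φ(e)

where `K_i, Q_i, M_i` are node-type-specific linear projections,
`W_att, W_msg` are relation-specific bilinear maps, and `μ` is a learnable
scalar prior per meta-relation.  Attention is softmax-normalized over each
target's in-neighbors (per head, across relations); the weighted message sum
passes through a type-specific output projection, a nonlinearity and a
residual connection.  The encoder stacks an input projection (ReLU + dropout),
`L` such layers, and concatenates all layer outputs into the final node
features (`Feat`, width `d_model`).

**Decoder.**  A pair `(drug i, disease j)` is scored by a two-layer fully
connected network on concatenated features:

    Score(i,j) = σ( W₂ · Dropout(ReLU(BatchNorm(W₁ [Feat_i ; Feat_j]))) )

**Training.**  Mini-batches are type-budgeted subgraphs sampled from seed
drugs (importance-weighted, so batches stay dense and type-balanced).  Each
batch's masked indications with both endpoints in the subgraph are the
positives; an equal number of uniform non-indicated drug×disease pairs are
the negatives.  Binary cross-entropy is minimized end to end with AdamW under
a cosine-annealed learning rate.  Defaults follow the published full-scale
setup (3 layers, 8 heads, width 64, 80% masking, 300 epochs, sampling batches
of 164 seed drugs with 512-node per-type budgets).

The neural network runs on a small reverse-mode autodiff engine written on
numpy (`hgtlink.autodiff`), validated against finite differences; no GPU or
deep-learning framework is required.

## Worked example

```bash
python examples/02_train_and_recover.py
```

generates the synthetic benchmark (100 drugs, 80 diseases, 200 proteins,
four latent blocks, within-block indication probability 0.30 vs 0.01
background, heavy-tailed degrees), trains the reduced model (2 layers,
width 16, 4 heads, 200 epochs, ~half a minute on one CPU) and prints:

```
benchmark graph: 380 nodes, 3214 edges, 647 indications (129 held out)
training loss: epoch 1 0.718 -> epoch 200 0.313
held-out AUROC (1:1 negatives): 0.870
full-pool ranking: AUROC 0.875, AUPR 0.146 over prevalence 0.0172 (lift 8.5x)
```

AUROC 0.870 means a held-out planted indication outranks a random unknown
pair 87% of the time; the AUPR lift of 8.5× over prevalence means early
precision in the ranking is far above a random ranker.  Other examples cover
graph construction and filtering (`01`), 5-fold cross-validation (`03`),
novel-pair ranking and relation retargeting (`04`) and the new-disease
scenario (`05`).

A thin command line wraps the same pipeline:

```bash
hgtlink simulate --seed 1 --out data/
hgtlink train    --graph data/edges.csv --embeddings data/ --config cfg.yaml --out run/
hgtlink evaluate --graph data/edges.csv --embeddings data/ --mode cv --out eval/
```

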