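"""Train the graph transformer on the synthetic benchmark and recover
held-out indications.

The generator plants a latent-block structure: drugs and diseases share
hidden classes, class-matched pairs are indicated with probability 0.30
versus 0.01 otherwise, and drug-protein / disease-protein relations are
correlated with the same classes.  A fifth of the planted indications is
held out; the model never sees them and must rank them above the unknown
pairs from graph context alone.

Takes about half a minute on one CPU.
"""

import hgtlink as hl

data = hl.generate(hl.SynthSpec(rng_seed=20))
g = data.graph
print(f"benchmark graph: {g.num_nodes()} nodes, {g.num_edges()} edges, "
      f"{g.num_edges('indication')} indications ({len(data.heldout)} held out)")

rec, eq, out = hl.run_benchmark(data, rng_seed=7)

losses = [r["loss"] for r in out.result.history]
print(f"training loss: epoch 1 {losses[0]:.3f} -> epoch {len(losses)} {losses[-1]:.3f}")
print(f"held-out AUROC (1:1 negatives): {eq.auroc:.3f}")
print(f"full-pool ranking: AUROC {rec.auroc:.3f}, AUPR {rec.aupr:.3f} "
      f"over prevalence {rec.prevalence:.4f} (lift {rec.aupr_lift:.1f}x)")
print("AUROC ~0.87 means a held-out indication outranks a random unknown pair "
      "~87% of the time; an AUPR lift well above 1 means early precision far "
      "exceeds a random ranker.")
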