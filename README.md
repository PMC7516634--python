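# motifemerge

Tools for studying how **network motifs** — small patterns of interconnection
that occur significantly more (or less) often than in randomized networks —
emerge in multi-layer perceptrons as a by-product of learning.

Deep networks start as stacks of fully connected bipartite graphs: before
training, no 3–5-node wiring pattern should be special. After training, the
weight distribution develops heavy tails; dropping the near-zero bulk of
weights leaves a sparse layered digraph whose over- and under-represented
subgraphs can be compared to those of biological signal-transduction
networks (diamonds, bi-fans, perceptron motifs). This package implements the
whole experimental loop:

1. **Synthetic learning environments** (`motifemerge.datasets`) — two
   31-feature, 4-class generative models: a *binary tree* model in which a
   ±1 value diffuses from the root with flip probability ε (hierarchical
   covariance), and an *independent clusters* model in which a spatial graph
   is annealed into four disjoint groups and each sample activates one group
   (block-diagonal covariance).
2. **MLP training** (`motifemerge.mlp`) — NumPy implementation of fully
   connected nets (ReLU hidden, softmax output) trained by mini-batch SGD
   with Nesterov momentum 0.6, learning rate 0.01 and inverse-time decay
   1e−6, under three weight initializations: Normal *N*(0, 0.1²),
   (semi-)orthogonal, and Glorot with variance k/(n_in + n_out), k = 2.
3. **Graph extraction** (`motifemerge.graph_extraction`) — a Gaussian is
   fitted to the pooled weights; weights whose fitted density exceeds
   `c`·(peak density) form the exclusion zone and are pruned. Survivors
   become directed edges categorized as strongly positive/negative (beyond
   ±2σ) or mild.
4. **Motif mining** (`motifemerge.motifs`) — exact ESU enumeration of
   weakly connected induced k-node subgraphs (k ≤ 5), exhaustive canonical
   labeling (optionally edge-colored by weight category), degree-preserving
   switch-randomized null ensembles, and the significance score

   Z = (N_real − ⟨N_random⟩) / σ_random

   per isomorphism class, plus before/after-learning profile deltas.
5. **Pipeline & CLI** (`motifemerge.pipeline`, `motifemerge` command) — the
   full grid (2 environments × 3 initializations), with CSV/GraphML/JSON
   artifacts and FANMOD-dialect edge lists.

## Worked example

```python
import numpy as np
import motifemerge as me

data = me.generate_tree_dataset(me.TreeConfig(n_samples=4000, seed=7))
arch = me.MLPArchitecture.from_preset("240120")          # 31-20-10-4
res = me.train(arch, data, me.TrainConfig(init_scheme="normal", seed=1))
print(res.epochs_to_perfect)                              # -> 3

cfg = me.PruneConfig()                                    # cutoff c = 0.26
before = me.model_to_graph(res.initial_params, cfg)
after = me.model_to_graph(res.final_params, cfg)
print(before.number_of_edges(), after.number_of_edges())  # -> 87 59

wb = np.abs([d["weight"] for _, _, d in before.edges(data=True)])
wa = np.abs([d["weight"] for _, _, d in after.edges(data=True)])
print(round(wb.mean(), 3), round(wa.mean(), 3))           # -> 0.204 0.535

null = me.NullModelConfig(n_replicas=200, swaps_per_edge=3, seed=5)
census = me.enumerate_connected_subgraphs(after, 4)
profile = me.z_scores(census, me.null_census_ensemble(after, 4, null))
print(me.top_motifs(profile, 3))
# -> [(392, 0.73...), (74, -0.56...), (76, -0.49...)]
```

Reading the numbers: training reaches perfect accuracy after 3 epochs; of
the 860 connections, 87 initial and 59 trained weights survive pruning; the
mean absolute retained weight grows from 0.204 to 0.535 — learning pushes
weight mass into the distribution tails. The final lines score each 4-node
motif class (identified by its canonical adjacency code) against 200
degree-preserving randomizations of the same layered graph.

The same loop from a shell:

```bash
motifemerge generate --kind tree --n-samples 4000 --seed 7 --out tree.csv
motifemerge train --arch 240120 --init normal --data tree.csv --out-prefix model
motifemerge extract --params model_final.json --out edges.txt
motifemerge mine --edges edges.txt --k 4 --replicas 200 --seed 5 --out profile.csv
motifemerge run-all --out results/   # the full 2x3 grid
```

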