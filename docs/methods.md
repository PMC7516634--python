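# Methods

## Synthetic learning environments

Both generators produce a design matrix of 31 features and integer labels
over 4 classes, so the same network architecture can be trained on either.

**Binary tree.** A depth-`D` binary tree (`2^D − 1` nodes, linear-array
layout: children of node *i* at `2i+1`, `2i+2`; default `D = 5`, 31
features) carries ±1 values. The root is uniform on {−1, +1}. Its +1 child
is deterministic: a +1 root promotes the left child, a −1 root the right
child, and the rest of the other subtree stays at −1. From level 2 down,
each +1 node passes +1 to its left child with probability `1 − ε` and to
its right child otherwise (`ε = 0.3` by default; smaller ε makes the +1
path straighter). Features of a sample are all node values. Consequences
used as test invariants: each level below the root holds exactly one +1
node, and every descendant of a non-root −1 node is −1.

The class of a sample is the identity of the +1 path down to level
`distinction_level + 1`. At the default distinction level 2 this is (root
sign, flip outcome at the unique level-2 +1 node), enumerated in the fixed
order (+1/no-flip, +1/flip, −1/no-flip, −1/flip) → (0, 1, 2, 3), with
analytic class probabilities (0.35, 0.15, 0.35, 0.15) at ε = 0.3. The
enumeration itself is a convention; any bijection would do. Deeper
distinction levels extend the recorded flip string and double the class
count per level.

**Independent clusters.** 31 nodes are scattered (Gaussian, spread 0.08)
around 4 well-separated centers — the corners of the unit square — with
group sizes (8, 8, 8, 7), and joined into a complete graph with Euclidean
edge lengths. A rising temperature schedule of `n` equally spaced values
from 1/(longest edge) to 1/(shortest edge) is applied; at each step, edges
of length ≥ 1/T are deleted. Annealing stops at the first step after which
the graph has exactly 4 connected components and no isolated node; if the
schedule exhausts without reaching that state (possible for unlucky
geometry), a fresh geometry is drawn, up to a bounded retry count. The
tight-spread / distant-centers layout makes the intra- and inter-group edge
length populations essentially disjoint, so the early-stop condition is
reached at the first threshold falling between the two populations and the
surviving edges are intra-group.

Within each group, the node closest to the group centroid is designated the
root (any unique in-degree-0 node would do); every node receives
topological order 1 + its unweighted distance from the root, and each edge
is directed from the lower-order endpoint to the higher (order ties from
the lower to the higher node id). A sample picks a group uniformly at
random; features of the chosen group's nodes equal their topological order,
all others are −1. All samples of a class are identical by construction —
a deliberately easy, linearly separable task whose feature covariance is
block-diagonal with a textured background.

Sample counts default to 4,000 per environment: small enough to train in
seconds, large enough that class frequencies are stable to a few binomial
standard errors.

What the generators do **not** emulate: real data has within-class
variability in the clusters environment (here there is none), sampling
noise beyond the generative randomness, and any feature-scale
heterogeneity. Tests passing on these environments therefore demonstrate
the machinery and the qualitative learning phenomena, not performance on
natural data.

## Network and optimizer

Architectures are fully connected stacks (presets `240120` = 31-20-10-4,
`250120` = 31-20-20-4, `180112` = 31-30-30-4; the preset name doubles as
the default RNG seed). Hidden units are rectifiers, the output is a
softmax, and the loss is categorical cross-entropy — the standard pairing
with a softmax output.

The optimizer is mini-batch SGD (batch 32) with Nesterov momentum 0.6,
initial learning rate 0.01 and per-update inverse-time decay
`lr_t = 0.01 / (1 + 10⁻⁶ t)`; the momentum update uses the legacy-Keras
form `v ← μv − lr_t g; w ← w + μv − lr_t g`. Biases start at zero. The
epoch budget is 200; both environments are learned to accuracy 1.0 within a
handful of epochs at these settings. Backpropagation is verified against
central finite differences (relative error < 10⁻⁵) on small random nets.

Initialization schemes:

* **normal** — i.i.d. *N*(0, 0.1²). The 0.1 is a standard deviation, not a
  variance: with σ ≈ 0.316 the mean absolute *retained* weight after
  pruning could not be as small as the observed ≈ 0.206, since the
  truncated-tail mean always exceeds the untruncated half-normal mean
  (≈ 0.25 at that σ).
* **orthogonal** — QR factorization of a Gaussian draw with the sign of
  `diag(R)` absorbed, giving an orthonormal shorter axis (rows for wide
  matrices, columns for tall).
* **glorot** — i.i.d. Gaussian with variance `k/(n_in + n_out)`; `k = 2`
  is the rectifier-appropriate gain.

Empirically (10 seeds, tree environment), the Normal scheme converges
slowest (median ≈ 3.5 epochs vs ≈ 1–1.5 for the other two), consistent
with its much smaller initial weights. The relative ordering of the
orthogonal and Glorot schemes is within noise at these problem sizes and
is not asserted.

## Weight pruning and graph extraction

A single Gaussian (sample mean μ, sample std σ) is fitted to the pooled
connection weights of all layers — the fit treats the weight histogram as
one population. The exclusion zone is the set of weights whose fitted
density is at least `c` times the peak density, i.e. the band
`|w − μ| ≤ σ·sqrt(2 ln(1/c))`; larger `c` shrinks the band. Retained
weights become directed edges (input → output) of a layered digraph whose
nodes are the network's units, numbered contiguously by layer. Biases are
not part of the graph: motifs concern inter-unit connectivity. Each edge is
categorized as strongly positive (w > μ + 2σ), strongly negative
(w < μ − 2σ), or mild; the 2σ multiplier is a conventional choice and is
configurable.

**Default cutoff `c = 0.26`.** The default is calibrated so that pruning a
freshly Normal-initialized network (σ = 0.1) leaves retained weights with
mean absolute value 0.206, the reference value for that configuration:
solving the truncated half-normal mean equation
`σ·φ(a)/(1 − Φ(a)) = 0.206` gives `a = t/σ = 1.642`, hence
`c = exp(−a²/2) = 0.260` (the function `calibrate_cutoff` reproduces this
computation). At this cutoff roughly 10% of the 860 connections of the
default preset survive pruning of an untrained Normal-initialized model.

## Motif mining

**Enumeration.** Connected induced k-node subgraphs (k = 3, 4, 5;
connectivity means weak connectivity of the directed subgraph) are
enumerated exactly once each by the ESU ordered-extension scheme: starting
from every node *v*, the extension set only ever admits exclusive neighbors
with a label greater than *v*. The implementation is validated against a
brute-force all-subsets oracle on random digraphs.

**Classification.** Isomorphism classes are identified by an exhaustive
canonical code: the minimum over all k! node permutations of the row-major
adjacency number in base 2 (uncolored) or base 4 (colored: cell values 0 =
no arc, 1 = mild, 2 = strongly positive, 3 = strongly negative). With
k ≤ 5 the 120-permutation minimization is exact; codes are memoized per
raw adjacency pattern. Colored classification is the weighted-analysis
mode; each colored class maps onto an uncolored skeleton, which defines
the isomorphic groups used when ranking (`most_significant` keeps the
group member with the largest |Z|, `most_typical` the member closest to
the group's mean Z).

**Null model.** Replicas are produced by attempted double-edge swaps
(a→b, c→d) ⇒ (a→d, c→b), `swaps_per_edge × |E|` attempts (default 3),
rejecting swaps that would create a self-loop or duplicate arc; in the
default `layer_preserving` mode a swap must also keep both new arcs on
consecutive layers, so replicas remain valid perceptron topologies. A
`global` mode without the layer constraint is available, since generic
motif tools randomize without structural constraints and the choice
materially changes Z values. In/out degrees are preserved exactly in both
modes; edge categories travel with the source half of each rewired arc,
approximately preserving per-node color degrees. Ensemble size defaults to
1,000 replicas (configurable; the statistics of interest stabilize well
below that for the graph sizes involved).

**Scoring.** Per class, `Z = (N_real − ⟨N_random⟩)/σ_random` with the
sample standard deviation over replicas; classes absent from a replica
count zero, and classes seen only in replicas are kept with `N_real = 0`.
Classes with `σ_random = 0` (e.g. when every replica equals the original)
have undefined Z and are excluded from profiles and deltas. Profiles are
deliberately **not** normalized — the same network is compared before and
after training, so raw magnitudes are informative. The before/after delta
is `Z_after − Z_before` per class, treating a class wholly absent from one
profile as Z = 0 there and propagating undefined values.

## Pipeline

`run_experiment` executes generate → initialize (snapshot) → train →
prune/extract (before and after graphs) → mine → profile/delta for the
grid of 2 environments × 3 initializations on one architecture (default
`240120`), writing datasets, parameter snapshots, edge lists, GraphML,
profile and delta CSVs, and a JSON summary. The "before" graph is always
extracted from the stored initialization snapshot, and both graphs are
pruned with the same configuration so that deltas compare like with like.
All stage seeds are derived deterministically from the single experiment
seed, making reruns byte-identical; a failure in one cell is recorded and
does not abort the rest of the grid.

## Numerical choices and degenerate inputs

* Softmax is computed with the max-shift trick; cross-entropy clips
  probabilities at 10⁻¹².
* Accuracy argmax ties break to the lowest class index.
* A constant weight population cannot be Gaussian-fitted and raises a
  degenerate-fit error; a zero-length spatial edge raises a
  degenerate-geometry error; an exhausted annealing schedule raises an
  annealing failure that the dataset generator absorbs by redrawing the
  geometry.
* An empty post-pruning graph is legal (0 edges, all nodes kept).
* `temperature_schedule` with all edge lengths equal returns a constant
  schedule, and a graph already split into the target number of groups is
  returned unchanged at step 0.

## Problem sizes

Tests and the acceptance script use the defaults above: 4,000-sample
environments, the 31-20-10-4 preset, 200-epoch budgets, 100 random
digraphs of ≤ 12 nodes for the enumeration oracle, and 200-replica
ensembles for null-model calibration checks. These sizes keep any single
check within seconds while leaving the statistical assertions several
standard errors of headroom.

## Known limitations

* Exhaustive enumeration only: no sampling-based (probabilistic) subgraph
  search and no k ≥ 6; practical up to roughly a thousand edges.
* Feed-forward fully connected architectures only; no convolutional or
  recurrent variants, and no GPU path (the networks have ≤ ~2,000
  parameters).
* The specific identities of the most significant motifs depend on the
  null-model mode, coloring, and ensemble settings; they are reported and
  plotted but treated as qualitative rather than asserted, and the
  orthogonal-vs-Glorot convergence ordering is likewise left unasserted.
* The statistical significance of before/after weight-distribution changes
  is summarized by directional statistics only; no hypothesis test is
  attached.
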