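# Methods

## Problem and model

The task is single-label multi-class classification of drug pairs:
every known interacting pair carries exactly one of R event classes,
encoded from a (mechanism, action) description. The pipeline has two
stages.

**Stage 1.** The known interactions form an attributed multiplex
network: one node set (drugs), one undirected simple-graph layer per
event class, no edge weights. Node attributes are rows of a drug–drug
Jaccard similarity matrix computed from one binary feature source
(chemical substructure, target, enzyme or pathway); a configuration
switch allows raw binary feature rows instead, but similarity rows are
the default because they give every source a common n-dimensional
attribute space. Per layer r, each drug i receives

    v_{i,r} = x_i W_b + B_i + (agg_r(x)_i W_e^r) M_r

- `x_i` — the attribute vector (length a = n for similarity rows);
- `W_b` (a × d) and free offsets `B` (n × d) — the base part, shared
  across layers;
- `agg_r(x)` — neighbor-mean propagation of the attribute matrix over
  layer r, 2 rounds by default; nodes isolated in the layer keep their
  own attribute row, so every drug has a defined edge part everywhere;
- `W_e^r` (a × s) — the per-layer attribute transform into a small
  edge space (s = 8 by default);
- `M_r` (s × d) — the learned lift from edge space to output space.

Parameters are trained by skip-gram with negative sampling over
uniform random walks confined to one layer at a time (no cross-layer
transitions). Context vectors are free per-node parameters initialized
at zero; negatives are drawn from the within-layer unigram
distribution raised to 0.75. Optimization is minibatch Adam. The
described architecture — attribute-parameterized base and edge
embeddings with per-layer aggregation and a learned lift — was one of
several ways to realize "base + edge embeddings with an attribute
transformation"; it was fixed as the package's design before tuning
anything downstream, and all sizes are configurable.

**Stage 2.** Per-drug tensors are flattened in event-id order
(F_i = [v_{i,1}, …, v_{i,R}]) and pairs fused by schema `a`
(element-wise product, symmetric, width d·R), `b` (concatenation in
canonical i < j order, width 2·d·R) or `d` (alias of `a`: computing
the product inside the classifier's input stage is numerically the
same function, and reported accuracy differences between the two are
attributed to training variance). One fully connected sub-network per
source — hidden stack with batch normalization, ReLU and dropout after
each hidden layer, softmax output — is trained with cross-entropy and
Adam against the shared labels; the ensemble output is the arithmetic
mean of the per-source softmax distributions (probability averaging,
not logit averaging). Early stopping monitors validation cross-entropy
on a stratified split of the training rows and restores best-epoch
weights.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| embedding dimension d | 32 | accuracy peaks here in the dimension sweep; 16 is nearly as good and cheaper |
| edge-space size s | 8 | internal per-layer width; output is rank-limited by s |
| walks per node / walk length / window | 20 / 10 / 5 | conventional for few-hundred-node graphs |
| negatives | 5 | skip-gram negative samples per positive |
| propagation rounds | 2 | neighbor-mean attribute diffusion depth |
| trainer batch / lr | 256 / 0.01 | small batches matter on tiny graphs: too few Adam steps underfit the edge part and layer vectors collapse onto the shared base direction |
| hidden sizes | (512, 256) | strictly decreasing ("bottleneck-like"); scaled down in tests |
| dropout / batch size / patience | 0.3 / 128 / 10 | patience counts epochs without validation-loss improvement |
| validation fraction | 0.1 | stratified; every class with ≥ 2 rows keeps ≥ 1 validation row |

Event ids are assigned by descending sample count with lexicographic
label tie-break — the frequency convention is a package choice (the
encoding of the ids is not otherwise determined) and an explicit
catalog can override it. Edges are undirected, stored canonically with
i < j, one event per unordered pair.

## Synthetic data: what it emulates, what it does not

The generator plants: latent drug classes; per-source binary
prototypes with independent bit-flip noise ε (so within-class Jaccard
similarity exceeds between-class for ε < 0.5); event labels that are a
deterministic function of the endpoint class pair (so topology and
attributes carry the same signal); and a power-law event-size profile
reproducing the heavy right skew of real event frequencies. Defaults
(400 drugs, 8 events, 4000 edges, ε = 0.1) keep a full 5-fold CV under
two minutes on one CPU; those sizes are the package's standard study
conditions, not tuned per run.

It does **not** emulate: correlated feature items, drugs that straddle
classes, label noise, non-transitive interaction structure, or the
512-plus-item sparsity patterns of real feature sources. Passing the
end-to-end tests therefore shows the pipeline recovers planted
class-pair structure through both stages; it does not certify
real-data accuracy.

Two planted regimes are used deliberately: a *balanced* event profile
for the parameter-recovery benchmark and its label-shuffled null
(chance level is then exactly 1/R), and the *power-law* profile for
the imbalance check, where an imperfect-accuracy regime (ε = 0.3) is
needed for the head/tail F1 ordering to be observable at all — at
ε = 0.1 every event saturates at F1 = 1.

## Evaluation protocol

Stratified k-fold over edges: events with ≥ k members are spread
round-robin after a seeded shuffle (a persistent cursor keeps overall
test sizes within one edge of each other); events with fewer members
are training-only and reported as such, since a test fold containing a
class the model never saw measures nothing. Metrics: accuracy from
argmax; micro AUC and micro AUPR on the one-vs-rest binarized matrix
flattened across the classes present in the test labels; macro
F1/precision/recall as unweighted means over present classes, with the
number of absent classes reported. Ranking ties use the average-rank
convention (scikit-learn's default). For single-label predictions
micro precision = micro recall = micro F1 = accuracy; the suite
asserts this identity exactly against a confusion-matrix oracle.

`transductive` mode is the default because it mirrors the original
stage ordering (embedding precedes CV); `inductive_safe` retrains
embeddings per fold on training edges only and is what the end-to-end
benchmark uses, since embedding-before-split is a known leakage risk.
Transductive accuracy is expected to be ≥ inductive on the same seeds.

## Numerical choices and degenerate inputs

- 0/0 Jaccard (two all-zero rows) is 0, not 1: no shared evidence.
  Diagonal forced to 1 by a convention flag (default on).
- Softmax is computed with max-subtraction; validation cross-entropy
  clips probabilities at 1e-12.
- Batch-norm inference uses running statistics (momentum 0.9);
  training batches of fewer than 2 rows are skipped.
- Layers with no edges contribute no walks or skip-gram pairs; their
  tensor slice is driven by the base/attribute pathway only. An edge
  list whose every layer is empty is rejected.
- One master seed fans out through `numpy.random.SeedSequence` to
  per-layer walk RNGs, trainer initialization, fold splitting and the
  validation split; identical inputs and seed give bit-identical
  similarity matrices, walks, tensors and CV reports.
- Seeds are masked to 31 bits before being combined.

## Known limitations

- Embeddings are transductive by construction: an unseen drug has no
  vector (no inductive inference path).
- The skip-gram trainer is single-threaded NumPy; it is sized for
  networks of hundreds of nodes, not the 10^5-node regime.
- Probability outputs are uncalibrated; the mean-of-softmax ensemble
  tends toward underconfidence.
- Schema `b` doubles feature width and memory; schemas involving
  external pairwise multiplication methods or sequence models over the
  two-dimensional embedding matrices are out of scope.
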