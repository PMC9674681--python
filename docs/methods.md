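# Methods

## Model

A graph set `𝒢 = {G_1, …, G_m}` contains undirected graphs `G = (A, X)`
with symmetric hollow 0/1 adjacency `A ∈ R^{n×n}` and node features
`X ∈ R^{n×d}`; `d` is shared across a dataset.  Each graph carries a binary
anomaly label used only for evaluation.

**Encoder.**  Two GCN layers
`Z_l = φ(D̃^{-1/2} Ã D̃^{-1/2} Z_{l-1} θ_l)` with `Ã = A + I`,
`D̃_ii = Σ_j Ã_ij`, no biases, widths `d → 256 → 128`, `φ = ReLU`.  The
graph-level readout `Z_G` is the coordinate-wise max of `Z_node` over valid
nodes.  Self-loops exist only inside the encoder; stored adjacencies stay
hollow.

**Perturbed twin.**  The second contrastive view uses the same encoder with
`θ́_l = θ_l + η·Δθ_l`, `Δθ_l ~ N(0, σ_l²)`, redrawn every forward pass.
`σ_l` is left free by the formulation; we set it to the empirical standard
deviation of `θ_l`'s entries at the moment of perturbation, which scales the
noise to each layer automatically (a constant override is available).  The
draw is treated as a constant: gradients flow into `θ_l` but never into the
noise.  At `η = 0` the twin is bit-identical to the plain encoder.  The
perturbed branch feeds only the contrastive loss — never the decoders, the
error loss, or the anomaly score.

**Projection head.**  One shared two-layer MLP (`128 → 128 → 128`, ReLU,
with biases) maps both readouts into the contrastive space.  The head is
used only there: the error losses and the anomaly score consume the raw
readouts, matching how the error terms are defined on `Z_G` rather than on
its projection.

**Decoders.**  Structure: `Â = sigmoid(Z_node Z_nodeᵀ)` (entries strictly in
(0,1); symmetric by construction).  Attributes: a two-layer GCN
(`128 → 256 → d`) running on the *original* graph's normalized adjacency —
the formulation prints the input graph's `Ã` here, and we follow it — with
a linear output layer so `X̂` can match arbitrary-signed features.

**Re-encoding.**  `(Â, X̂)` is passed through the same (unperturbed) encoder
object; `Â` enters as a continuous weighted adjacency with self-loops added
and degrees equal to row sums.  No thresholding: binarizing `Â` would cut
all decoder gradients.  If `(Â, X̂)` equals `(A, X)` exactly, the re-encoded
representations are bit-equal to the originals (shared parameters).

## Losses

* `L_recon = ‖A − Â‖²_F + ‖X − X̂‖²_F`, per graph over valid entries, then
  averaged over the minibatch so batch size does not rescale the objective.
  Diagonal adjacency entries are excluded: self-loops are an encoder device,
  not data.
* `L_contrast`: for anchor `i`, numerator `exp(sim(Ẑ́_i, Ź_i)/τ)` with
  cosine similarity and temperature `τ`; the denominator sums over the
  `N − 1` other graphs of the minibatch.  The textual description of the
  formulation draws negatives from the perturbed view and the printed
  formula from the plain view; both are implemented
  (`negatives="perturbed"`, the default, vs `"unperturbed"`) and the
  discrepancy is documented rather than resolved.  The positive pair is
  excluded from the denominator, so the loss may be negative; it is not
  clamped.  One direction only (anchor = plain view), as printed.
* `L_node`: mean over graphs of the per-graph mean over valid nodes of
  `‖Z_node,i − Ź_node,i‖²`; `L_graph`: mean of `‖Z_G − Ź_G‖²`;
  `L_error = L_node + L_graph`.  During training the mean runs over the
  minibatch; at inference the score is strictly per-graph.
* `L_total` is the unweighted sum.  Ablation flags (`cl`, `node`, `graph`)
  drop individual terms; there are no weighting coefficients.

**Score.**  `Score(G) = (1/|G|) Σ_i ‖Z_node,i − Ź_node,i‖² +
‖Z_G − Ź_G‖²`, computed with the unperturbed encoder only, hence
deterministic given a trained state.

## Training protocol

Normal graphs only (a contract violation raises).  Defaults: Adam, learning
rate 1e-4, batch 300, 100 epochs, `η = 1`, `τ = 0.2`.  Minibatches are
reshuffled per epoch under the run seed; a trailing batch of size 1 is
dropped (no negatives).  Optimizer state is reset per fold; no early
stopping.  Evaluation uses stratified k-fold splits: the model trains on
the normal graphs of k−1 folds and scores the full held-out fold, so every
test fold contains anomalies and AUC (midrank convention) is defined.
Stratification is our choice — a plain shuffle can produce anomaly-free
test folds on small sets.  Repeated runs reshuffle folds *and* reseed
initialization (seed + repeat index).  Test batches are padded to the full
dataset's maximum node count so train and test share geometry.

Everything runs single-threaded NumPy double precision; two runs with the
same config and seed produce bit-identical checkpoints and scores.

## Synthetic benchmarks

The generators emulate the two structural anomaly classes the method
targets, with exact ground truth:

* **Motif sets.**  Normal graph = 3-ring + 4-ring joined by one bridge
  edge; with probability `jitter` one benign chord is added (default 0 in
  the API; the standard benchmark uses 0.1 so normal graphs are not all
  isomorphic).  *Local* anomaly: all links of one non-bridge 4-ring node
  are rewired onto two distinct 3-ring nodes — node count unchanged, the
  4-ring destroyed, the graph still connected.  *Global* anomaly: a
  two-node pendant path attached to the 4-ring, changing the whole-graph
  pattern.  *Attribute* anomaly: normal topology, features
  `N(μ_shift, 1)^4` against `N(0, 1)^4` (default shift 2) — a minimal
  controllable feature signal.  Structural sets carry degree one-hot
  features (width = dataset max degree + 1).
* **ER contrast sets.**  Normal `G(n, p_normal)`, anomalous
  `G(n, p_anomalous)`.  Features are *scalar* degrees, not one-hots: with a
  continuous density control the one-hot width would be dictated by the
  densest (anomalous) graphs, whose indicator columns the one-class
  training never exercises; the encoder would map them through untrained
  weights to near-zero representations and the error score would collapse.
  Scalar degrees keep the feature support shared, so the benchmark measures
  structural deviation rather than feature-support leakage.

What the generators do **not** emulate: chemistry (valence, atom types,
bond orders), size heterogeneity of real screens (real molecular sets mix
7–200-node graphs), correlated attribute/structure anomalies, and label
noise.  Passing these benchmarks shows the mechanism ranks planted
structural deviations correctly at small scale; it does not certify
performance on any real compound library.

## Standard problem sizes

The packaged benchmarks (`gladc.benchmarks`, used by the examples, the
acceptance script and the slow tests) fix: motif — 400 normal + 80 local
anomalies, jitter 0.1; ER — 200 + 40 graphs on 20 nodes, p 0.15 vs 0.6;
null — same with p 0.15 vs 0.15.  Training uses the default
hyperparameters with 50 epochs and minibatches of 64, which is ample for
7–22-node graphs; evaluation is one stratified held-out fold (of k = 5) per
seed, averaged over three seeds, except the null control which uses full
5-fold cross-validation to stabilize an AUC that should sit near 0.5.

## Numerical and design notes

* Glorot-uniform initialization everywhere; GCN layers have no biases (as
  printed), all MLP layers do.
* Max pooling backpropagates to the first argmax on ties (subgradient
  convention); padded rows are −∞ before the max and therefore never win.
* Padded nodes get degree 1 from the self-loop during normalization — with
  zero features and no biases their representations stay exactly zero, and
  outputs are re-masked after every layer anyway.
* Isolated valid nodes likewise have `D̃_ii = 1`; no division by zero is
  possible.
* Degree-0 nodes are valid in the degree one-hot encoding (column 0).
* The anomaly-class mapping for public datasets is always caller-supplied:
  the anomaly convention varies per dataset and a silent default would be
  wrong more often than right.
* Checkpoints are single versioned `.npz` containers (all weights + config
  echo); loading is bit-faithful.

## Known limitations

* Dense `O(M²)` padded batches: fine for molecule-scale graphs (tens of
  nodes), wasteful beyond a few hundred nodes per graph.
* Out-of-support node features defeat the score (see the ER encoding note
  above): the method assumes test-time feature support overlaps training.
* AUC on a single small fold is noisy; the null control's per-fold AUC can
  wander well away from 0.5 (variance, not signal), which is why it is
  reported cross-validated.
* The contrastive denominator ambiguity (perturbed vs plain negatives) is a
  documented fork of the formulation; both variants are available, and on
  the packaged benchmarks they behave indistinguishably.
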