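# Methods

## Problem setting

Health-insurance fraud rarely shows up in the attributes of a single claim:
fraud rings share behaviour — several card holders turning up in the same
department on the same day, or cycling the same prescriptions.  This package
models a year of claims as an attributed heterogeneous information network
(AHIN) with four node types — Patient (P), Time (T, calendar days),
Medicine (M), Department (D) — in which each visit contributes P–D, P–T and
per-medicine P–M edges tagged with the visit they came from.  Only patient
nodes carry a feature vector X ∈ R^(n×k); the other node types are purely
structural.

## Behavioural relation graphs

For every non-empty subset S ⊆ {D, T, M} a patient–patient relation graph is
built: patients i and j are neighbours iff *one visit of each* jointly
matches on every entity type in S (department equal, date equal, medicine
sets intersecting — all on that single visit pair).  The seven graphs are
PDP, PTP, PMP (level 1), PDTP, PDMP, PTMP (level 2) and PDTMP (level 3);
conjunction makes higher levels nested subsets of compatible lower levels,
which the tests assert against a brute-force pairwise-visit scan.

Two semantic choices deserve note:

* **Per-visit-pair conjunction.** Sharing a department in January and a
  date in March does *not* create a PDTP edge.  The alternative reading
  (conditions satisfied anywhere in the two patients' histories) would make
  the multilevel graphs nearly as dense as the single-level ones and
  destroy the sparsity that motivates the hierarchy.
* **Medicine condition = non-empty intersection**, not set equality: one
  shared dispensed medicine suffices.

Adjacency is unweighted for the model; the number of witnessing visit pairs
is retained per edge for diagnostics.  A `max_neighbors` knob (default
unlimited) randomly down-samples neighbour sets for large inputs, restoring
symmetry by keeping the union of surviving directions.

## Network

Three nested attention aggregations map features to a patient embedding H
(dimension d = 64):

1. **Intra-relation** (per relation l, K = 8 heads of width d/K):
   `e_ij = LeakyReLU(a_l^k · [W_l^k x_i ‖ W_l^k x_j])` with slope 0.2,
   softmax over the attended set (neighbours plus an always-present
   self-loop, which keeps the softmax defined for isolated patients), head
   output `ELU(Σ_j α_ij W_l^k x_j)`, heads concatenated.  Scores use the
   projected features; the concatenation order keeps e_ij asymmetric.
2. **Inter-relation**, within each level: relation score
   `ω_l = mean_i q0 · tanh(W0 x_i^l + b0)`, weights β = softmax(ω) *within
   the level* (3, 3 and 1 relations, so the triple level's β is identically
   1), level embedding = Σ β_l x^l.
3. **Hierarchical**: the same form with (W1, b1, q1) over the three level
   embeddings, giving level weights γ and H = Σ γ_m x_m.

The read-out head is a one-hidden-layer MLP (width 64, ELU, dropout) on H
producing two logits; `classifier_hidden = 0` switches to a plain linear
map.  The loss is class-weighted mean cross-entropy over the labelled
nodes; class weights default to inverse training-frequency normalised to
mean 1 (equal weights are one switch away), and the L2 penalty (λ = 0.001)
is applied by the optimiser as weight decay on weight matrices and
attention vectors, never on biases.

Training is transductive and full-batch: Adam (lr 0.005), dropout 0.6 on
the input features, on every α matrix and on the classifier hidden layer
during training only.  Early stopping uses the conjunction rule: stop when
neither the validation loss has made a new minimum nor the validation
accuracy a new maximum for 50 consecutive epochs (cap 400 epochs; typical
runs stop after 120–230).  The returned parameters are those of the epoch
with the lowest validation loss, earliest on ties.  Node splits are
stratified per class by largest remainder and seeded.

Defaults in one place: d = 64, attention vector width d_att = 128, K = 8,
lr 0.005, weight decay 0.001, dropout 0.6, patience 50, one aggregation
hop.  All are exposed in `TrainConfig`.

## Numerical implementation

The network is trained with a small reverse-mode automatic-differentiation
engine written for this package (`mhamfd/_autodiff.py`): tensors wrap numpy
arrays, and the operation set is exactly what the architecture needs
(broadcasting arithmetic, batched matmul, masked/plain/log softmax,
ELU/LeakyReLU/tanh, dropout, row gathering) plus an Adam optimiser with
coupled weight decay.  The attention score→softmax step, the hot spot, is a
single fused forward/backward kernel pair (numba-compiled, with a numpy
fallback).  Two precision regimes coexist: the training loop runs float32
(`TrainConfig.dtype`), every oracle-facing and reporting path float64.
Gradient correctness is asserted by central finite differences (step 1e-6,
relative tolerance 1e-4 with the comparison scale floored at the
finite-difference noise level 1e-6); architectural correctness by an
independently coded dense-matrix forward implementation (tolerance 1e-5)
kept deliberately loop-based and separate from the engine.

Degenerate inputs: a patient with no neighbours attends only itself
(α = 1); a level with one relation gets β = 1 exactly; all-identical
features give exactly uniform α over every attended set.  Attention
reports (α, β, γ and their pre-softmax scores) are taken from the
deterministic forward pass, before attention dropout, so every reported
α row sums to 1.

## Synthetic study populations

The claim data this model targets is private, so the package generates
populations that reproduce its structure rather than its values
(`mhamfd/synth.py`).  Fraud patients are partitioned into rings; each ring
receives `co_visits_per_ring` events in which every member visits the same
department on the same date (`signal_level` picks the shared entity types:
1 = date only, 2 = department and date — the default, 3 = department, date
and medicines).  Everyone additionally receives uniform background visits.
Features are standard normal; with the default class shift μ = 0 they carry
*no* label information, so anything a classifier learns must come from the
visit structure — the mechanism the model exists to exploit.

Default conditions: 100 fraud / 200 normal patients (the balanced 1:2
regime; 5 fraud / 350 normal reproduces the ~1:70 imbalanced regime), 60
departments, 180 dates, 200 medicines, rings of 6 with 3 co-visits,
2 background visits per patient, 2 medicines per visit, k = 32 features.
The universe sizes were chosen so that single-entity overlaps are common
(PDP/PTP/PMP have thousands of edges at n = 300 and are weakly informative)
while *joint* department-and-date coincidences are rare — conjunction
graphs stay sparse and fraud-enriched, the regime the hierarchy is designed
for.  Under these conditions the dual level carries most of the class
signal, and the fitted level-attention γ concentrates on it; the triple
level (PDTMP) is nearly empty at signal_level 2 — the few edges it does
have come from ring co-visits that coincidentally share a medicine, which
is why patients with a fraudulent PDTMP neighbour are strongly enriched for
fraud in the lift analysis.

What the generator does **not** emulate: billing amounts, diagnosis codes,
longitudinal disease trajectories, informative patient attributes, and
temporal drift.  A passing test suite therefore shows that the pipeline
recovers planted co-visit structure under label-free features; it does not
certify performance on real claims, where attributes and structure are both
informative and noisier.

## Evaluation and lift analysis

Metrics (accuracy, precision, recall, F1) treat fraud as the positive class
and are plain confusion-matrix arithmetic; undefined ratios are reported as
0 with a warning.  The fraud-lift table groups labelled patients per
relation by their count of labelled-fraud neighbours (buckets 0 / 1 / 2 /
3+) and divides each bucket's fraud rate by the zero-bucket's; when the
zero bucket is empty or fraud-free the overall fraud rate is the reference
and the row is flagged.  In null checks (shuffled labels) lifts are
estimated as ratios of rates pooled across shuffles — the mean of
per-shuffle ratios is biased upward when the reference group is small — and
only groups with a mean size of at least 10 are interpreted; smaller groups
are sampling noise at n = 300.

## Scope and limitations

* One aggregation hop (the architecture is a single intra/inter/hierar
  pass); the layer count is intentionally not a tuning surface.
* Full-batch dense attention: memory is O(K n²) per relation, fine up to a
  few thousand patients, not for city-scale populations without the
  neighbour cap.
* Baseline graph architectures, hyper-parameter sweeps and t-SNE figure
  generation are out of scope; embeddings are exported as TSV for any
  external visualisation tool.
* The raw patient attribute content is unspecified in this domain; the
  structural fallback (visit counts, distinct departments/medicines/dates,
  mean medicines per visit, z-scored and zero-padded) is a stand-in and is
  flagged as such in reports.
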