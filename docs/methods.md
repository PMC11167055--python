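# Methods

## Problem and model

`stitchgat` assesses six suturing sub-skills per stitch — needle
repositioning (RP), needle hold ratio (HR), needle hold angle (HA), needle
driving smoothness (DS), wrist rotation (WR) and wrist rotation at needle
withdrawal (WRnw) — jointly rather than in isolation. The motivation is
that sub-skill quality is correlated across the sub-phases of a stitch, so
information about a surgeon's hold ratio, driving smoothness or wrist
rotation is genuinely informative about their hold angle.

The pipeline has two stages.

**Stage 1 (per-sub-skill encoding).** Each sub-phase clip is encoded into a
128-dimensional feature vector and an independent probability of ideal
performance. Two encoder paths exist. The `small_conv_stub` path is a
random-feature convolutional encoder — fixed, seeded random filter banks
over appearance frames and dense optical-flow fields (computed with an
iterative Lucas–Kanade method), ReLU, global average pooling, exponential
temporal pooling, and a fixed random projection — with only the logistic
classification head trained (Adam, learning rate 1e-3, 50 epochs). It runs
from raw frame arrays on one CPU in seconds and is what the tests exercise.
The second path bypasses encoding entirely and trains the head on
precomputed (or synthetic) feature vectors; this is the primary pipeline
path, since the model downstream of stage 1 never needs raw video. The
trained stage-1 head is also the "independent" arm of every comparison.

**Stage 2 (joint assessment).** Each sub-skill is a node of a fixed 6-node
prior graph whose undirected edges encode the previously established
sub-skill associations: HR–HA, HA–DS and HA–WR (self-loops are implicit on
every node, so RP and WRnw participate as isolated nodes). A node's input is
the stage-1 feature concatenated with its flattened, aligned kinematic
sequence; at the published defaults that is 128 + 70 × 24 = 1808 dimensions.
A single-head graph-attention layer then updates each node:

    h_i   = W x_i + b                      (shared linear map, width 1024)
    e_ij  = a2' LeakyReLU(A1 [h_i ‖ h_j] + b1)     (scorer, width 1024, slope 0.2)
    α_ij  = softmax over {j : A_ij = 1} of e_ij    (masked softmax)
    h'_i  = ELU( Σ_{j: A_ij=1} α_ij h_j )
    z_i   = W_o h'_i + b_o                 (projection, width 128)
    logit_i = H_i z_i + c_i                (node-specific 2-way head)

Training minimizes the sum over the six nodes of the cross-entropy against
the binary labels (1 = ideal) with Adam, learning rate 1e-3, batch size 32,
50 epochs. Stage-2 training never touches stage-1 parameters.

Ablation switches reproduce the two baselines: `use_attention=False`
replaces α by weight one on every allowed entry (an unnormalized sum,
reading "strength fixed to one" literally; a mean-aggregation variant is
available behind `no_attention_aggregation="mean"`), and
`use_kinematics=False` zeroes the kinematics block of every node input
while keeping the dimensionality contract.

Design points that were genuinely open and how they were settled:

* **W and the scorer are shared across nodes** (standard single-head GAT);
  node identity enters through the inputs and the per-node heads. This
  keeps the 6-node model small.
* **Scorer shape**: one hidden layer with LeakyReLU (slope 0.2) before the
  masked softmax, following the standard GAT formulation.
* **Aggregation nonlinearity** is ELU; the projection is linear. The
  width sentence "hidden 1024, output 128" is read as: GAT hidden width
  1024, then a projection to 128, then per-node linear heads to 2 logits.
* **Edge set** excludes HA–WRnw: the explicit enumeration lists exactly
  three pairs, and the edge list is a config field so an alternative graph
  is one line away.
* **Optimizer** Adam without weight decay; batch size 32 for stage 2 and 16
  for stage 1 (unspecified upstream).
* The model is implemented directly in NumPy with hand-written backprop;
  gradients are finite-difference checked in the test suite, and the
  forward pass is checked against an explicit nested-loop aggregation
  oracle. At six nodes and one layer this is faster to audit than a
  framework dependency.

## Kinematic preprocessing

Raw logs carry, per frame, ten tracked poses (position + quaternion, 70
scalars) and the camera pose. Preprocessing is: (1) select the log rows
whose `frame_id` appears in the clip's frame-id list (ids are join keys,
not positional indices); (2) re-express every pose in the camera frame —
position `R_c^-1 (p - p_c)`, orientation `q_c^-1 ⊗ q` with the Hamilton
product on scalar-first quaternions, unit-normalized after composition;
(3) divide positions by the maximum distance from the origin over the clip
(so the max norm is exactly 1, or 0 for a degenerate all-zero clip, which
is passed through flagged rather than raised); (4) fix the length to 24
frames by uniform-index subsampling (first and last retained, no
interpolation) or last-frame padding; (5) flatten frame-major to 70 × 24 =
1680 values.

Decisions: normalization is **per clip**, not per dataset, so test-time
preprocessing does not depend on the training corpus; the camera
composition is applied to **both** positions and orientations; quaternion
convention is (w, x, y, z). The transform-then-normalize pipeline is
invariant to a rigid motion applied simultaneously to all poses and the
camera, which the tests verify by brute force.

## Evaluation

Cross-validation is leave-one-institution-out: with five institutions, five
folds, each training on four institutions and scoring the held-out fifth,
so generalization across medical centers is what is measured. The metric
is the stitch-level AUC per sub-skill (midrank Mann–Whitney form; ties get
half credit), summarized as mean ± standard deviation across folds with the
population (n-denominator) convention so printed ± values are exactly
recomputable. The MEAN row averages the six sub-skills within each fold
first, then takes mean/std across folds. Model selection is the final
epoch; no early stopping.

Utilities: PABAK (2·observed agreement − 1) for binary inter-rater
reliability, computed pairwise with pooling left to the caller; calibration
curves over equal-width probability bins (empty bins omitted, counts sum to
n).

## Skill–outcome association

Case-level skill scores are the surgeon's mean predicted ideal-probability
per domain over their stitches (median available). Univariable logistic
regressions give one exponentiated coefficient per domain — an odds ratio,
reported under the "rate ratio" label used in this literature — with Wald
95% CIs and p-values; complete separation is flagged, not silently
diverged. The multivariable model adds age, BMI, PSA and prostate volume
(rank-checked design), and its predicted probabilities feed the ROC/AUC.
The AI-vs-human comparison is reported descriptively (two AUCs side by
side), with no formal test.

## Synthetic cohort generator

The real multi-institution VR dataset is restricted, so the generator
emulates its statistical structure: five institutions, surgeons nested in
institutions, and per-surgeon latent abilities z ∈ R^6 drawn from a
multivariate normal whose correlation is `edge_corr` exactly on prior-graph
edges (positive-definiteness checked at construction). Per stitch, latent
factors f = z + stitch-level jitter; the label for sub-skill k is

    y_k = 1{ γ f_k + Σ_{j∈N(k)} β_kj f_j + ε  >  τ_k },

with τ_k set analytically to hit the configured prevalence (default 0.5).
The β terms are the planted cross-sub-skill structure the joint model is
designed to exploit; `cross_signal` is a scalar on every edge or a directed
mapping for asymmetric planting. Features are informative about the **own**
latent factor only (x_k = f_k w_k + institution shift + noise), so neighbor
information is reachable only through neighbor nodes. Institution
heterogeneity is an affine per-institution feature shift plus a
per-institution multiplier on β. Kinematic streams are smooth random walks
with unit quaternions and a camera pose; half of the tracked points move
with an amplitude that carries a weak monotone trace of the latent factor
(a relative-amplitude signal chosen to survive per-clip normalization).
An outcome table draws continence recovery from
`logit(P) = α0 + Σ_k α_k · mean-skill_k + covariate terms` with recorded
coefficients.

Default condition: 5 institutions × 8 surgeons × 25 stitches, edge
correlation 0.4, cross-signal 0.5, own-signal 1.0, threshold noise 0.5,
institution jitter 0.3. Planted-recovery experiments use the same cohort
shape with cross-signal 1.2 (or 1.5 on a single directed edge for the
attention test), zero edge correlation (so the independent baseline cannot
proxy neighbors through correlated abilities) and own-signal 0.6. What the
generator does **not** emulate: realistic video content, biomechanically
plausible needle trajectories, rater noise in labels, and class imbalance
beyond the prevalence knob — so passing tests demonstrate that the
machinery recovers planted statistical structure, not that it matches
clinical effect sizes.

## Problem sizes and numerical choices

Test and demonstration runs use deliberately compact sizes chosen as the
smallest at which the statistical contrasts of interest are stable:
16-dimensional stage-1 features, kinematic target length 4 (node input
296), GAT widths 32/16/16, 50 epochs for the recovery experiments, and a
200-stitch quickstart at 30 epochs. The published widths (128-d features,
24-frame kinematics, 1024 hidden) remain the defaults of `JointConfig` and
are exercised by the dimensional-contract checks. Masked softmax subtracts
the row max over allowed entries before exponentiation; disallowed entries
are exactly zero by construction, never by thresholding. All randomness
flows from one integer seed through named substreams (CRC-based), and
reruns at a fixed seed reproduce metric JSON byte for byte.

## Known limitations

* At quickstart scale (200 stitches) the high-capacity joint model
  overfits its 280-dimensional kinematics block and trails the logistic
  independent baseline; the joint advantage appears at the study-shaped
  1000-stitch cohorts with planted cross-signal, which is the regime the
  method targets.
* The single-layer sum aggregation pays a signal-to-noise cost on
  high-degree nodes (HA aggregates four inputs), so the joint model does
  not reach the oracle that reads concatenated neighbor features.
* Attention-strength recovery is statistical, not guaranteed per seed: the
  head can partially compensate for misallocated attention, so planted
  orderings are asserted across seeds.
* The stage-1 stub is a random-feature encoder; it demonstrates the
  interface and the training loop, not representation learning.
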