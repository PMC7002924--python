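# Methods

`mdimportance` extracts per-feature and per-residue importance from
conformational ensembles: given trajectory frames (optionally labeled with
a metastable-state index per frame), it ranks input features by how
strongly they distinguish states or dominate variance, and maps those
ranks back onto atoms or residues. This note documents the models, the
synthetic benchmark, the numerical choices, and what the tests do and do
not establish.

## Featurization

Frames are converted to one of three feature sets:

- **Cartesian**: the raw 3N coordinates, deliberately *not* superposed —
  robustness to the absence of alignment is part of what the benchmark
  probes.
- **Inverse interatomic distances, full**: all N(N−1)/2 reciprocal pair
  distances. Inverse distances emphasize short-range (contact) geometry
  and are rotation invariant.
- **Inverse distances, reduced**: only pairs (i, i+k), k ≤ 4 — the
  smallest internal-coordinate set that still triangulates every atom's
  position in the chain.

For real trajectories, residue-pair distances are computed with MDTraj
(`scheme="ca"` for Cα–Cα, `scheme="closest-heavy"` for the minimum
heavy-atom distance per residue pair). Two filters operate on *raw*
distances (nm) before inversion:

- **Contact-change filter**: keep a pair iff its distance is below the
  cutoff in at least one frame and above it in another — i.e. the contact
  forms and breaks within the data set.
- **Range filter**: drop pairs that stay above the upper bound or below
  the lower bound throughout.

All features are then min–max scaled to [0, 1] per feature (the scaling
record is kept for inversion; constant features are flagged, mapped to 0
and dropped before model fitting, since zero variance breaks both scaling
and histogramming). Optionally samples are shuffled in contiguous blocks
(labels co-permuted) to decorrelate fold assignment from trajectory time
while preserving local correlation inside blocks.

## The six estimators

All estimators emit importance normalized to an upper bound of 1.

**PCA** — unsupervised. With normalized eigenvalues λ_j and loadings
T_ij, importance is R_i = Σ_{j<j_max} |λ_j T_ij|. Three stopping criteria
for j_max: a fixed count; the smallest leading set whose cumulative
variance reaches a threshold θ; or an eigengap rule that stops after the
first component whose eigenvalue exceeds the next by a factor (default
10). The eigengap rule tends to retain all components of comparable
variance, which outperforms using only the first PC.

**KL divergence** — supervised, model-free. Per feature and state, the
in-state histogram P and rest-of-data histogram Q share bins of width
1% of the observed range (configurable); importance is the symmetric
divergence ½KL(P‖Q) + ½KL(Q‖P) in nats. Empty bins receive a 10⁻⁹
pseudocount before normalization so the logs stay finite; fully disjoint
distributions therefore saturate at a finite value set by that
pseudocount. Per-state rows are normalized to max 1, averaged into the
ensemble profile, and renormalized.

**Random forest** — supervised. Gini mean-decrease-impurity importance
from scikit-learn forests, either one multiclass forest or one binary
forest per state (one-vs-rest), which yields state-specific profiles.
MDI spreads importance unevenly across correlated informative features —
the forest can classify perfectly while using only a subset of them — so
RF profiles are sparse: excellent at ignoring irrelevant atoms, weaker at
finding *all* important ones. Accuracy grows with the number of trees
(more trees → denser coverage of the informative set).

**MLP + LRP** — supervised. A scikit-learn MLP classifier (ReLU, Adam)
is trained, then layer-wise relevance propagation redistributes each
frame's true-class output probability back to the inputs. This is the
only family that yields *per-frame* importance. Two training caveats
matter and are reflected in the defaults:

- sklearn's default stopping tolerance halts training within a few epochs
  on separable data, while weights are still near their random
  initialization; relevance read off such a network is almost flat. The
  default here trains further (`tol=1e-7`-ish, fixed epoch budget).
- For binary problems sklearn uses a single logistic output; for LRP this
  head is expanded into the equivalent two-column softmax [−w, +w] so
  that class-0 relevance propagates along inhibitory paths.

`n_fits` averages per-frame relevance over several independently
initialized classifiers; the initialization-dependent part of the
relevance background cancels while the signal persists. This is the
iteration-averaging step of the analysis checklist applied inside a
single importance computation.

**Autoencoder + LRP** — unsupervised. An MLP regressor trained with the
input as its own target, symmetric encoder/decoder shapes enforced. LRP
runs from the reconstructed output (all outputs masked with ones) to the
input. Because biases absorb no relevance, outputs whose reconstruction
is bias-dominated still redistribute their full seed through whatever
small weights exist — AE profiles are therefore the noisiest of the six,
and the estimator is practical only after aggressive feature reduction.

**RBM + LRP** — unsupervised. A Bernoulli restricted Boltzmann machine
(stochastic maximum likelihood) whose hidden-unit activation
probabilities seed the relevance, propagated through the single logistic
layer with the bounded-input rule. Inputs must lie in [0, 1] and are read
as activation probabilities — physically sensible for scaled inverse
distances (contact ⇒ value near 1), not for Cartesian input. A learning
rate near 1 destabilizes training and triggers a warning.

## The LRP engine

Backward relevance propagation through dense feedforward stacks, per
sample. Output relevance is initialized as R_i = T_i·T′_i (one-hot label
times output). One layer down:

    R_j = Σ_k z_jk / (s_k + ε·sign(s_k)) · R_k,   s_k = Σ_j z_jk

with ε = 10⁻⁹ stabilizing near-zero denominators and biases excluded from
redistribution. Rules: z⁺ (z_jk = a_j·max(0, w_jk)) for unbounded layers;
z^B (z_jk = a_j·w_jk − l_j·max(0,w_jk) − h_j·min(0,w_jk)) for the input
layer when the input is bounded in [l, h], e.g. min–max scaled data. For
ReLU networks this is the deep Taylor decomposition. Softmax/logistic
output nonlinearities affect only the seed magnitude, not the backward
rules (which use activations and weights only).

Properties the tests pin down: conservation of total relevance per layer
for nonnegative z and ε→0; proportionality to the seed; zero relevance
for zero-activation inputs under z⁺; and exact agreement with an
independent loop-based reference implementation on small networks. A
practical consequence of z^B worth knowing: inputs the network never uses
keep their (L2-decayed but nonzero) random weights and receive a
weight-magnitude baseline through the −h·min(0,w) term; bounded-input
relevance therefore has a floor that z⁺ does not have.

## Per-atom aggregation

An atom's raw score is the sum of the importance of all features
involving it (both endpoints of a pair; the x,y,z triplet of a Cartesian
atom). Scores are then min–max normalized onto [0, 1]. The subtraction of
the minimum matters with dense feature sets: every atom participates in
~N distances, a sizeable fraction of which are genuinely state-dependent
(any distance from a displaced atom to anything changes between states),
so the raw sums carry a large shared baseline; min–max removes it, while
a pure max-division (available as `normalization="max"`) preserves true
zeros but leaves the baseline in place.

## The synthetic benchmark

`toy_model` generates systems with known ground truth: atoms placed
uniformly in a cube (half-width 1.0), states defined by displacing
disjoint per-state atom subsets — linearly (one shared vector of norm
0.1 per state) or nonlinearly (a chain of rotations about preceding
atoms; angle π/4·(state+1) about a configurable axis, as a helix-twist
analogue). Frames are i.i.d. draws: displaced geometry + uniform noise
(amplitude 0.01) on **all** atoms' coordinates, then a uniformly random
rotation about the origin (unit-quaternion sampling). Defaults: 100
atoms, 3 states × 10 displaced atoms, 1200 frames per state.

What the generator emulates: state-dependent contact changes, thermal
jitter, and the absence of a global alignment. What it does not: temporal
correlation (frames are independent), Boltzmann weighting, anisotropic or
correlated noise, and any real force-field geometry. Tests passing on the
toy model therefore demonstrate that an estimator recovers known
displaced atoms under these idealized conditions — not that it will rank
residues correctly in a specific real system.

Two scores compare a measured per-atom profile φ with the ground truth ψ
(indicator of displaced atoms, ℓ2-normalized; φ is ℓ2-normalized for
scoring as well, which bounds both scores by 1):

- **find-all** = 1 − ‖ψ̂−φ̂‖₂ / (‖ψ̂‖₂+‖φ̂‖₂): high only if *every*
  displaced atom carries importance and little mass sits elsewhere.
- **ignore-irrelevant** = φ·ψ̂ / ‖φ‖₂: high if importance sits *only* on
  displaced atoms, not necessarily all of them. Note this equals the
  cosine of φ and ψ and is symmetric in value; the asymmetry between the
  two arguments is one of domain (an all-zero φ degrades to score 0, an
  all-zero ψ is invalid).

`run_benchmark` crosses toy instances × repeats × methods × feature kinds
(plus a uniform-random baseline), recording both scores in long format
with box-plot summaries (median, IQR, 1.5·IQR whiskers, outlier counts).
`hyperparameter_scan` grids a single method over it.

### Benchmark hyperparameters

The defaults in `default_method_suite` follow a grid scan on separate toy
instances, per input kind, mirroring the protocol's advice to pick the
best-performing set per setup: RF 2000 trees; KL 1% bins; PCA eigengap;
MLP hidden (30,) with `n_fits=3` for distance input, and a single wide
hidden layer (1500,) with α=10⁻² for Cartesian input — deep narrow stacks
diffuse relevance over the long backward path, while a wide shallow net
keeps it sharp, and the rotated-coordinates task needs that width to fit
rotation-robust decision surfaces at all.

### Problem sizes

Quantitative suite results quoted in the README come from a scaled-down
benchmark: 3 toy instances, 200 frames per state, 3 repeats per
instance (9 scores per cell), with the standard geometry (100 atoms, 3
states × 10 displaced, displacement 0.1, noise 0.01). The observed
qualitative ordering — all supervised methods strong on inverse
distances; PCA at or below random on rotated Cartesian input while the
MLP stays clearly above it; RF better at ignoring irrelevant atoms than
at finding all of them — is stable at this size.

## Analysis presets

Three bundled recipes document the real-system workflows: `cam`
(calmodulin C-terminal domain: Cα inverse distances, 1.0 nm
contact-change filter, block shuffle of 100 frames, PCA at 75% cumulative
variance, AE/MLP hidden layers built from (120, 100), RF 500 trees
one-vs-rest, 3-fold CV × 5 iterations), `gpcr` (β2 adrenergic receptor:
Cα inverse distances, PCA eigengap, RF 1000 trees, 4-fold × 30
iterations) and `vsd` (Kv1.2 voltage sensor: closest-heavy-atom residue
distances, 0.5–0.7 nm range filter, RF 100 trees, 3-fold × 5 iterations).
The AE's symmetric hidden stack for `cam` is realized as (120, 100, 120)
— encoder (120, 100), decoder mirrored, shared 100-unit bottleneck. The
presets ship no external data; they assume the user supplies trajectory
and labels.

## Numerical and design choices

- Random rotations: uniform over SO(3) via unit quaternions.
- Noise: independent uniform per Cartesian component (the plain reading
  of "uniform noise" at these amplitudes).
- ε placement: added to the redistribution denominator with the
  denominator's sign; ε=0 raises on an all-zero denominator.
- LRP seeds: post-activation class probabilities (not pre-softmax
  scores). The alternative seeding with logits changes only the scale of
  per-frame relevance, not its normalized profile.
- KL: natural log; shared bin edges spanning the pooled per-feature
  range; number of bins = round(1/bin_width_fraction).
- PCA cumulative-variance criterion includes the smallest leading set
  whose Σλ reaches the threshold.
- Profile normalization divides by the maximum, or by max |value| when no
  positive mass exists (mixed-sign relevance); all-zero profiles are
  returned as zeros with a flag.
- Degenerate inputs: coincident atoms (zero distance) raise with frame
  and pair named; empty states raise; single-class label sets raise;
  infeasible toy configurations (overlapping important sets) raise.
- Cross-validation (`run_repeated`): each iteration reshuffles samples
  into k folds; the estimator refits per training split; held-out
  accuracy is recorded for multiclass classifiers (one-vs-rest binary
  accuracies against multiclass labels are not meaningful and are
  skipped). Profile mean is renormalized to max 1; the per-feature
  standard deviation is reported unnormalized.
- Indices are 0-based internally and 1-based in PDB output; B-factor
  projection writes importance × 100 clamped to [0, 99.99].

## Known limitations

- The z^B relevance floor means LRP-based profiles on bounded inputs
  never reach exact zero for unused features; rankings are meaningful,
  absolute values near the bottom are not.
- AE importance is unreliable for wide inputs (hundreds of features or
  more) and for data containing near-constant features.
- RBM importance assumes the probabilistic input reading; applying it to
  Cartesian input is supported for comparison but not meaningful.
- MDI-based RF importance systematically under-covers correlated
  informative features; use one-vs-rest and many trees to mitigate.
- The toy benchmark's i.i.d. frames make cross-validation optimistic
  relative to autocorrelated real trajectories; block shuffling is the
  provided mitigation, not a cure.
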