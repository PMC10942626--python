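# Methods

This note records the model, the estimators, the numerical choices, and
the known limitations of the package, in the order the pipeline runs.

## EMG preprocessing

Raw EMG (trials × muscles × samples) is full-wave rectified, low-pass
filtered with a zero-phase Butterworth filter (20 Hz cut-off; order 4
before the forward-backward pass, so the effective magnitude response is
order 8 — the order is a config parameter, as the standard recipes leave
it implicit), cubic-spline resampled to 1000 time samples, and integrated
over consecutive 20-sample windows, giving 50-step envelopes. The chain
order is enforced by a validator: filtering before rectification would
remove the very high-frequency content rectification is meant to fold
into the amplitude. Window integration uses sums rather than means
("integration" denotes accumulation; constant factors are irrelevant to
rank-based estimators anyway). No amplitude normalisation is applied:
every downstream estimator is invariant under strictly monotone marginal
transforms, so per-muscle scaling is immaterial. Task signals (kinematics
etc.) are cubic-spline resampled onto the same time base.

## Information estimators

All entropies are computed in nats internally and converted to bits at
the interface. Margins are rank-mapped to standard normal via
`Φ⁻¹(rank/(n+1))` with average ranks for ties (deterministic and
permutation invariant). Gaussian entropies carry the psi-function
small-sample bias correction; at the trial counts typical of one
participant-task cell (a few hundred) the bias is not negligible.

- `I(mx; my)`: Gaussian-copula MI from bias-corrected entropies.
- `I(mx; τ)`, discrete τ: class-conditional Gaussian model on the
  copula-normalised data — overall entropy minus class-weighted
  conditional entropies. Note a structural property of this model family:
  because the rank transform maps the pooled data to a standard normal,
  perfectly separated equiprobable binary classes yield exactly
  `−½log₂(1 − 2/π) ≈ 0.73` bits, not the full 1 bit of H(τ). The
  estimator is a conservative task-information index, bounded by H(τ) and
  exactly zero under independence.
- `I(mx; my | τ)`, discrete τ: class-weighted copula MI with *within
  class* rank renormalisation, because conditioning changes the margins.
- Continuous τ: the closed-form Gaussian conditional MI on the
  copula-normalised triple.
- Co-information is assembled from the three *unclipped* component MIs so
  the additive identity `I(mx;my;τ) = I([mx,my];τ) − I(mx;τ) − I(my;τ)`
  holds exactly per call; the components are recorded on the returned
  estimate. MI and CMI values reported on their own are clipped at zero.
- The exact plugin estimator over empirical joint frequencies serves the
  discrete worked examples (copula estimators are undefined on
  constant-within-class data).

Negative co-information is net redundancy, positive is net synergy; the
redundant and synergistic tensor classes are the rectified negative and
positive halves, produced in one pass so they are never jointly positive.

For continuous task variables and a timepoint pair (t1, t2), marginal
MIs use the task sample at each member's own timepoint and the joint term
uses the stacked pair [τ(t1), τ(t2)] (deduplicated on the diagonal).
This pairing policy is a package choice; the alternative (a single shared
timepoint) is a one-line change in `coupling._tau_slices`.

## The coupling tensor

All unordered muscle pairs (self-pairs excluded — self-MI is an entropy,
not a coupling) × all timepoint pairs (diagonal included — temporally
proximal dependencies live there) × (task variable × participant) layers.
Layers are indexed (task, participant) in row-major order and labelled,
so coefficient matrices stay interpretable. The tensor re-slices
losslessly into spatial (muscle × muscle) or temporal (time × time)
symmetric adjacency stacks.

## Percolation sparsification

Within each layer, edges are removed in ascending weight order while the
giant-component fraction is tracked against "equivalently sized random
networks" — the same layer with weights shuffled over the same edges, so
that removing the k weakest null edges removes a uniformly random
k-subset. Removal stops at the first step where the empirical fraction
drops below the null summary (mean by default; a lower percentile is a
config option) at the same density; the percolation threshold Pc is the
weight of the last removed edge. Removal order is made deterministic by
breaking weight ties on edge index; null curves are computed with a
reverse union-find so a whole curve costs O(E α(n)).

The stopping rule alone cannot empty a layer whose weights are pure
noise: removal always leaves a spanning core. Significance therefore has
a second, layer-wise ingredient: the mean gap between the empirical
removal curve and the null-ensemble mean is used as a permutation
statistic (strong couplings concentrated on a subnetwork strand the
remaining nodes once the weak scaffold is gone — earlier than any
weight-shuffled null). The add-one permutation p-values are corrected
across a view's layers with Benjamini-Hochberg at rate 0.05; only
significant layers contribute surviving edges. This adaptive correction
is what makes the procedure both sensitive (structure present in many
layers lowers the effective threshold) and specific (under the global
null the familywise discovery probability is at most the FDR rate).

An entry of the tensor is retained only if its edge survives in its
spatial layer AND its temporal layer. Diagonal (t, t) entries are
self-loops that cannot affect connectivity; they are exempt from removal
and survive the temporal test whenever positive. A power fact worth
knowing: a *single* strong pair in an otherwise random layer is
topologically undetectable by any weight-shuffle percolation test (the
removal curve is exchangeable with its nulls); detection requires the
coupling structure to span a subnetwork, which is exactly the regime of
interest for muscle synergies.

## Model-rank selection

Monolayer modularity is the Newman-Girvan Q-statistic
`Q = (1/2m) Σᵢⱼ (Aᵢⱼ − kᵢkⱼ/2m) δ(gᵢ,gⱼ)` with `m = ½ΣA`; the multilayer
form adds categorical all-to-all inter-layer coupling ω with
normalisation `2μ = Σ_l ΣAₗ + Σ couplings`, so a single layer reduces
exactly to the monolayer value and identical layers with ω = 0 give the
mean of the per-layer values. γ = ω = 1 throughout (classical
modularity; no hyperparameter tuning). Optimisation is a seeded
Louvain-style scheme — greedy local moves alternating with community
aggregation — with restarts, lowest-index tie-breaking, and the
all-in-one partition as a floor candidate.

Ranks come from a consensus: per participant/task group, community
detection on the multiplex stack (multilayer route) and on each matrix
(monolayer route) produce partitions; co-classification binaries are
stacked into a new multiplex network and detection is re-applied. The
consensus community count is the model rank, computed separately for the
spatial and temporal orientations. Both routes are reported; the
multilayer result is the default and disagreements are recorded in the
rank's provenance rather than silently resolved.

## Tri-factorisation (sNM3F)

`A[k,t,l] ≈ Σᵢⱼ S[l,i,j]·W[i,t]·V[j,k]` with nonnegative shared temporal
factors W, shared spatial factors V, and layer-specific coefficients S —
an all-to-all pairing: any spatial network may combine with any temporal
pattern at a participant/task-specific weight. S is the participant- and
task-specific scaling of information overlap, **not** variance accounted
for. Fitting uses multiplicative updates (objective monotone
non-increasing), uniform-random nonnegative initialisation, best of 10
restarts, convergence at relative objective change < 1e-6 or 500
iterations (both exposed; the recovery experiments in the test suite run
2000 iterations at 1e-8 for tight residuals). A small orthogonality
penalty (1e-4) on the spatial factor Gram matrix discourages duplicate
spatial factors; the temporal penalty defaults to 0. An optional binary
mask excludes entries from the objective — this is how the ablation
protocol "removes" columns without changing factor shapes.

Identifiability: like all NMF-family models the factorisation is unique
only up to permutation and scaling, and *dense* factor sets admit
genuine rotational freedom inside the nonnegative cone. Factor matching
(greedy maximum-correlation assignment) is therefore part of the
evaluation layer, never of the fitter. The comparator is an in-house
masked multiplicative-ALS non-negative CP decomposition (one-to-one
factor pairing) at rank max(spatial, temporal).

## Subnetwork analysis

Node importance is total communicability `C(i) = Σⱼ[e^A]ᵢⱼ` (scipy
`expm`). "Below-average" pruning operates on *edges*: an edge is kept iff
its `e^A` entry reaches the mean over existing edges (node-level pruning
would disconnect muscles outright); exactly one pass, ties at the mean
kept, with a 1e-9 relative tolerance absorbing matrix-exponential
round-off. Spatial factors map onto muscle networks directly (they are
indexed by muscle pairs); submodules come from monolayer detection.

## Generalisability protocols

Leave-one-out removes one participant's (or task's) layers, refits at
the same rank, matches factors greedily by Pearson r, and reports per
comparison r. Random ablation repeats 50 times: a uniformly random
number (1 … columns−1) of (timepoint-pair, layer) column vectors is
excluded from the fitting objective via the mask. Summaries go through
Fisher's Z (atanh → mean/sd → tanh); because the back-transformed sd can
exceed the correlation bound, the Z-scale sd is reported alongside.
Similarity is computed separately for spatial and temporal factors;
coefficients S are excluded (the objects compared are the networks).

## Synthetic data

The generator emulates trial-structured envelope tensors with planted
couplings; defaults mirror a single-arm reaching study (7 participants,
640 trials, 9 muscles, 50-step envelopes, 2-class task, unit noise).
Classes are planted as:

- redundant — both muscles driven by one task-dependent latent (the
  centred class code, or per-group class-effect vectors orthogonalised
  across groups so that distinct groups carry independent task
  dimensions);
- synergistic — parity coding for discrete tasks (one muscle a random
  bit, the other the bit XOR the class: marginals carry nothing, the
  pair everything); complementary-component coding for continuous tasks
  (the task tracks the *sum* of two latents carried by different
  muscles, giving net-positive co-information). A multiplicative
  interaction was rejected: it leaves no second-moment signature, and in
  the Gaussian-copula score space zero marginal correlation with both
  muscles implies zero joint information, so product-coded synergy is
  invisible to this estimator family by construction;
- irrelevant — a shared latent independent of the task.

Envelope nonnegativity comes from a softplus of the latent sum, which is
strictly monotone and therefore invisible to the estimators. Everything
is drawn from one seeded generator; identical specs give byte-identical
data.

What the generator does *not* emulate: motor-unit physiology, electrode
crosstalk, nonstationary noise, inter-muscle amplitude scaling, or
realistic kinematic trajectories. Passing tests demonstrate that the
pipeline recovers the statistical structure it is designed to detect,
not that any particular biological dataset contains such structure.

## Problem sizes used in the validation suites

The recovery and robustness experiments run at desk scale, chosen to be
the smallest sizes at which each statistical property is identifiable:
9 muscles / 10 envelope steps with planted modules spanning about half
the montage (a realistic synergy extent; percolation retention and
false-positive control at 2000 trials), rank-(3, 2) factor recovery on
15 × 10 × 6 tensors, and 5-participant leave-one-out / 50-iteration
ablation runs at 800 trials with an 8-class task.

## Known limitations

- The class-conditional Gaussian mixture MI saturates below H(τ) for
  highly separable classes (see above); comparisons across conditions
  remain valid, absolute values are conservative.
- Percolation significance needs coupling structure spanning ≥ ~4 nodes
  per layer to have power at typical montage sizes.
- The tri-factorisation rank must come from the rank-selection stage;
  the fitter performs no automatic rank choice.
- Continuous task variables enter per-timepoint; cross-lag couplings
  between muscle activity and *future* task values are not modelled
  beyond the stacked-pair policy.
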