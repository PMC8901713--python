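# Methods

`cogflex` implements the four analysis stages of a two-condition
within-subject cognitive-flexibility experiment — semantic-network
estimation from free responses, percolation robustness, conflict-diffusion
modelling of Stroop data, and mouse-trajectory macro-state analysis —
together with the permutation-based paired inference that ties them to the
design, and a synthetic-data generator that emulates the statistical
structure of such a study.

## Paired inference

All condition comparisons use a two-tailed paired-samples permutation
t-test: the observed paired t is computed from the differences
`d_i = a_i − b_i`, and the null distribution is built by flipping the sign
of each difference independently per iteration (the standard sign-flip
scheme for paired designs). The p-value uses the add-one convention
`(1 + #{|t*| ≥ |t|}) / (n_iter + 1)`, so p is never exactly zero and the
test remains valid at any iteration count. Monte-Carlo agreement with
exhaustive sign-pattern enumeration is checked in the tests. Effect size
is Cohen's `d_z = mean(d)/sd(d)`; the `d_av` variant (difference of means
over the average condition SD) is available because the literature is
split on which paired variant to report. All-zero differences return
`p = 1, t = 0` rather than raising, so resampling loops never abort on
degenerate iterations.

Presence/absence comparisons of unique-response inventories use McNemar's
test with the continuity correction `(max(|b−c|−1, 0))² / (b+c)` (the
correction is clamped at zero when `|b−c| < 1`), and φ = √(χ²/n) as
effect size. The continuity-corrected variant is the default because it is
the one that reproduces the reference worked example of this design; the
uncorrected branch is exposed and cross-checked against statsmodels.

## Semantic networks

Free responses are lowercased and passed through a user-supplied
normalization map (identity by default). Spell-checking is deliberately
not built in: a locale-dependent spell-checker inside the pipeline would
make results irreproducible; the map is the reproducible hook for it.
Responses are encoded per condition as a binary participants × responses
incidence matrix (duplicate tokens from one participant collapse to a
single 1). Only responses given by ≥ 2 participants in *both* conditions
are retained (matched node sets), edges are cosine similarities between
the participant-incidence columns, and the dense network is filtered with
the Triangulated Maximally Filtered Graph: greedy seeding with a heavy
4-clique (heaviest edge, then twice the vertex with maximal weight into
the clique — the standard greedy stand-in for the exhaustive max-weight
4-clique, which is O(n⁴)), followed by repeated insertion of the vertex
that adds maximal weight into an existing triangular face. The result is
planar and connected with exactly 3(n−2) edges. TMFG edges whose cosine
weight is exactly zero are kept as structural edges (an explicit adjacency
mask), so the binarized graph stays connected.

Topological quantifiers are computed after binarization: mean local
clustering coefficient (transitivity exposed as an option), unweighted
average shortest path length, Louvain modularity with a fixed seed
(networkx's implementation), and small-worldness. For S the
Humphries–Gurney normalized ratio `(CC/CC_rand)/(ASPL/ASPL_rand)` with the
analytic Erdős–Rényi baseline (`CC_rand = 2m/(n(n−1))`,
`ASPL_rand = ln n / ln(2m/n)`) is used: a plain CC/ASPL ratio cannot
produce small-worldness values near 4–5 from CC ≈ 0.69 and ASPL ≈ 3.4,
so the normalized form from the small-world literature is adopted; a
sampled G(n,m) baseline is available by config.

Inference uses two resampling schemes. Leave-one-node-out recomputes the
metrics on the already-filtered network with one node removed (no
re-filtering), pairing conditions by the removed node label — possible
because the matched node sets coincide. Leave-one-subject-out re-runs the
*entire* pipeline (threshold, matching, cosine, TMFG) without one
participant, pairing by participant. Iterations whose partial network is
disconnected or too small are skipped with a warning rather than patched
with harmonic-mean path lengths, keeping the iteration sets honest.

## Percolation

Networks are attacked by removing all edges with weight below an
increasing threshold. The threshold starts at the smallest edge weight
and advances by the smallest positive gap between distinct weights
(duplicates at 1e−9 tolerance; if that resolution would require more than
200,000 grid steps it is coarsened to fit, with a warning — cosine weights
of binary vectors can differ by arbitrarily little). At each step the
largest-connected-component size is recorded as a fraction of n (making
the integral comparable across leave-one-out partial networks of
different sizes); recording stops before the first step whose largest
component has fewer than 3 nodes. The percolation integral φ is the
threshold-weighted sum of the recorded LCCS values by default; a
trapezoidal area-under-curve convention is a config switch. The
implementation computes components once per distinct weight with a
reverse union–find and evaluates the grid vectorially; tests pin it to a
from-scratch enumeration oracle.

The link-shuffling null exchanges the weights of two randomly chosen
distinct edges, 10 × |E| times, leaving the topology and the weight
multiset untouched — this isolates the contribution of the weight
*arrangement* to robustness. 500 shuffled replicates per network are
paired across conditions by iteration index.

## Conflict diffusion model

The decision variable superimposes a controlled process with constant
drift δ and an automatic process whose expected time-course is a rescaled
Gamma density `E[A_t] = α e^{−t/τ} (t e/((θ−1)τ))^{θ−1}` with shape θ = 2
fixed, so the peak of `E[A_t]` equals α exactly at `t* = (θ−1)τ`. The
automatic drift is the analytic derivative
`μ_a(t) = E[A_t]((θ−1)/t − 1/τ)` (pinned to a finite-difference oracle in
tests). One diffusion noise source with σ = 4 acts on the superimposed
process; α is positive on congruent and negative on incongruent trials.
Boundaries sit at ±β (upper = correct), the starting point is a symmetric
beta(sp_shape, sp_shape) rescaled to (−β, β), and a Gaussian non-decision
time (clipped at zero) is added to the first-passage time.

Simulation is Euler–Maruyama at dt = 1 ms (default), with drift evaluated
at step-start times and `μ_a(0) = 0` by continuity. The core consumes
bulk-generated PCG64 noise in a numba-compiled early-exit loop, which
keeps a 4000-trial simulation near 10 ms. Trials not absorbed by t_max
are censored: excluded from the CDF, counted as errors in the CAF at
t_max. Discretized barrier crossing overshoots the boundary by
O(σ√dt), which biases absorption probabilities slightly; the constant-
drift closed-form check therefore runs at dt = 0.05 ms, where the
residual bias is comparable to Monte-Carlo error at 50,000 trials.

Fitting minimizes a pooled RMSE over the RT CDF (correct trials at the
10/30/50/70/90th percentiles) and the conditional accuracy function
(5 RT-quantile bins), for both congruency cells jointly with shared
parameters and α's sign switched by congruency, plus a *delta block* —
the incongruent-minus-congruent CDF and CAF differences — because those
differences carry the signature of the automatic process and would
otherwise be drowned by per-cell residual noise. CDF residuals are
divided by the observed correct-RT interquartile range so millisecond
residuals pool sensibly with proportion residuals.

The search is staged: uniform random candidates in a bounded box; the
best are re-scored at refinement precision and a small set of
*diversified* starts (minimum spread in the unit box) seeds Nelder–Mead.
Simplex runs use a box-scaled initial simplex (the scipy default of
±5% of the start point cannot traverse the box) and common random
numbers, so each loss evaluation is a deterministic function of the
parameters. Because the loss surface is multimodal in α — a strong,
brief automatic process can mimic a weak, sustained one — the refined
solution is re-run from a low-α and a high-α profile start. The final
parameter set is chosen among all candidates by re-evaluation with fresh
common noise, which stops the winner from being whichever run best
overfitted its own refinement stream, and guarantees the returned loss
beats every stage-1 winner at final precision. Two budget profiles are
built in: the full protocol (5000 sets × 5000 trials, 15 best refined 3×
at 10,000 trials, 200 simplex iterations) and a desk profile
(500 × 1000, 2 diversified starts refined deeply at 2500 trials with up
to 600 evaluations, plus the two profile runs) sized for interactive
runs and the test suite; recovery quality under the desk profile is what
the acceptance tests certify. The search box (α ∈ [0,40],
τ ∈ [20,300] ms, δ ∈ [0.1,1.0], β ∈ [20,150], non-decision mean
∈ [200,500] ms, sd ∈ [0,80] ms, sp_shape ∈ [1,5]) is configuration, not
constants.

Stroop preprocessing excludes participants below a 50% accuracy floor in
any condition, then removes trials outside median ± 3·MAD of RT computed
globally across all remaining trials (raw MAD, not the 1.4826-scaled
variant — the scaled variant does not reproduce a ±181 ms band from a
MAD-based rule at a 774 ms median).

## Mouse trajectories

Only correct, outlier-surviving trials are analyzed. Motion extraction
keeps samples that moved on both coordinates (literal reading; an
either-coordinate mode is exposed). Trajectories are linearly
interpolated onto 101 equally spaced time points and affinely mapped per
coordinate so every path runs from (0,0) to (1,1). Metrics: unsigned
shoelace area between the path and the ideal diagonal (AUC; the sign
convention is not fixed by the field, and comparisons are on magnitudes);
Bandt–Pompe permutation entropy per coordinate (m = 5, delay 1, stable
tie-breaking, normalized by log m!); direction changes as sign flips of
successive differences with zeros skipped; Euclidean path length; and
mean velocity (path length over the trial's original duration — after
time normalization a true-time dwell measure is no longer available, so
dwell times below are reported in grid samples).

Macro-states come from Gaussian mixtures with full covariances fitted to
the pooled (x, y) points of all trajectories (both conditions pooled, so
state labels are shared; an (x, y, t) feature variant is a config
switch), EM with tol 1e−3 and up to 1000 iterations, k from 2 to 10.
A candidate k is disqualified if any participant has a cluster with no
hard-assigned points; among qualifying k the minimum AIC wins. Clusters
are labeled Initiation / Prediction / Evaluation / Termination by the
ascending mean time index of their points when k = 4. Transition matrices
pool consecutive-label pairs within condition × congruency and
row-normalize (rows without outgoing transitions stay zero and are
flagged); dwell times average maximal run lengths within a trajectory
first, then across trajectories containing the state.

## Synthetic data

The generator is first-class, tested code standing in for raw data that
experiments of this design rarely release. Defaults encode the reference
experimental conditions: 52
participants, two condition arms, 64 Stroop trials per session at 50%
congruent, 100 Hz mouse sampling, and questionnaire items with planted
standardized effects of realistic magnitude for this manipulation (e.g. 2.63 for
imagery, 2.85 for strangeness). Condition effects are generative knobs,
not copied outcome values:

- **Free responses** are drawn from a Zipf-weighted vocabulary organized
  in concept blocks; each participant favors two blocks. The
  altered-perception-like arm ("DD") has a higher popularity exponent,
  more between-block mixing, and a *consensus core*: half its responses
  come from the most popular tokens, so a sizable group of participants
  shares a common response backbone. The mixing flattens the block
  structure (lower ASPL, higher small-worldness), and the consensus core
  gives the network many strongly overlapping incidence vectors — a dense
  spectrum of high cosine weights whose largest component survives to
  high thresholds, hence a larger percolation integral under the
  threshold-weighted-sum convention. A shared-vocabulary rate controls
  cross-condition overlap; at 0 the matched-response set is empty and
  generation fails with an explicit error.
- **Stroop sessions** are simulated from the conflict-diffusion model
  itself with per-condition ground-truth parameters (α = 25 vs 12 by
  default), stored in a sidecar JSON for recovery tests.
- **Trajectories** are four Gaussian hover phases (start, first guess,
  evaluation, target) in normalized start-to-target coordinates, mapped
  out to a four-target screen layout. Each phase mixes a smooth AR(1)
  component with white tremor; both are Gaussian, so the pooled point
  cloud is genuinely a four-Gaussian mixture (what the state model should
  recover), while the tremor share — higher in the DD arm and on
  incongruent trials — drives permutation entropy and direction changes
  without moving the cluster geometry. Incongruent first guesses are
  pulled toward the distractor box (raising AUC). Every trial has exactly
  101 raw samples (1.01 s at 100 Hz), so the 101-point time grid
  coincides with the raw samples and interpolation is exact; letting the
  grid up-sample shorter trials would blend neighboring samples into a
  variance mixture that an iid-likelihood mixture model reads as extra
  clusters.
- **Ratings** are paired normals with a participant random effect,
  truncated to [0, 1] by clipping; the truncation bias at extreme planted
  effects is accepted and visible only as attenuated realized effects.

What the generator does **not** emulate: real response semantics (tokens
are abstract), sequential/learning effects across trials, the joint
coupling between Stroop RTs and the trajectories of the same trials
(generated independently), pixel quantization of the cursor, and
participant-level correlations across stages. Passing tests therefore
certify the pipeline's correctness and its sensitivity to planted effects
of realistic size — not conclusions about any real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced but structurally
faithful problem sizes chosen as desk-scale defaults: conflict-diffusion
recovery uses 20 synthetic participants at 1000 trials per cell under the
desk budget; state-model selection uses 4 participants × 12 trajectories
per arm; direction checks use the full 52-participant response generator
and 4–6 participants for the fitted stages. Permutation tests default to
10,000 iterations in the pipeline and use 199–999 iterations inside
calibration loops (with the add-one convention the rejection rule
`p ≤ 0.05` is exact at these counts). Degenerate inputs throughout
(all-equal weights, zero-variance differences, stationary trajectories,
all-zero differences) return documented conventions or explicit errors
rather than NaNs.

## Known limitations

- The TMFG seed clique is greedy, not the exhaustive max-weight 4-clique;
  on adversarial weight matrices the retained weight can be slightly
  sub-optimal (structural guarantees are unaffected).
- With θ fixed at 2 the automatic process peaks at t = τ; other shapes
  are accepted by the data structures but untested.
- δ and β estimates from the staged fit carry upward relative bias of
  order 10–20% at desk budgets; the acceptance tests bound it at 25%.
- Dwell times are in 101-grid samples, not milliseconds, by construction
  of the time normalization.
- The percolation grid coarsening (beyond 200,000 steps) departs from
  the strict smallest-gap rule on near-continuous weight sets; the
  weighted-sum integral changes negligibly because the curve is a step
  function evaluated on a finer-than-step grid either way.
- The threshold-weighted-sum φ depends on each network's own threshold
  resolution (the smallest gap between its distinct weights), so its
  absolute scale is not comparable across networks with very different
  weight spectra; the trapezoidal convention is resolution-free and is
  the better choice when comparing networks whose weight sets differ
  structurally. The weighted sum remains the default because it is the
  convention the integral is defined with.
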