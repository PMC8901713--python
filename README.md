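# cogflex

Analysis pipeline for two-condition within-subject experiments on
**cognitive flexibility** — the capacity to shift between concepts and to
inhibit automatic responses. Given free responses to an alternative-uses
task (AUT), mouse-tracked Stroop trials, and questionnaire ratings
collected once per condition from the same participants, the package
estimates and compares, between conditions:

- **Group-level semantic networks**: responses become nodes, cosine
  similarity of their participant-incidence vectors becomes edge weight,
  the Triangulated Maximally Filtered Graph (TMFG, a planar subgraph with
  3(n−2) edges retaining maximal weight) removes spurious links, and the
  binarized network is summarized by the clustering coefficient CC, the
  average shortest path length ASPL, Louvain modularity Q, and the
  normalized small-worldness S = (CC/CC_rand)/(ASPL/ASPL_rand).
- **Percolation robustness**: edges below an increasing weight threshold
  are removed; the percolation integral φ (the sum of
  largest-component fractions weighted by their thresholds) indexes how
  slowly the network breaks apart.
- **Conflict-diffusion model (DMC)**: Stroop RT/accuracy is fitted with a
  drift-diffusion process whose drift superimposes a controlled component
  δ and an automatic component with a rescaled-Gamma mean time-course
  E[A_t] = α·e^(−t/τ)·(t·e/((θ−1)τ))^(θ−1) (amplitude α positive on
  congruent, negative on incongruent trials), by staged random search +
  Nelder–Mead on the RMSE between simulated and observed RT CDFs and
  conditional accuracy functions.
- **Mouse-trajectory macro-states**: 101-point normalized trajectories
  yield curvature (AUC), permutation entropy, direction changes, path
  length and velocity; Gaussian-mixture clustering with AIC model
  selection segments them into Initiation / Prediction / Evaluation /
  Termination states with transition matrices and dwell times.

All comparisons use two-tailed paired-samples permutation t-tests
(sign-flipping, 10,000 iterations by default) with Cohen's d, or McNemar's
χ² with φ for paired presence/absence counts. A synthetic-data generator
with planted condition effects stands in for raw data, so the entire
pipeline runs and is testable without any download.

## Worked example

```python
from cogflex import stats, semnet, percolation, synthetic

# McNemar on unique-response proportions: 196 responses exclusive to one
# condition, 228 to the other, 143 shared
counts = stats.ContingencyCounts(discordant_a_only=196,
                                 discordant_b_only=228,
                                 concordant_both=143)
res = stats.mcnemar_test(counts)
print(f"chi2(1) = {res.statistic:.3f}, p = {res.p_value:.3f}, "
      f"phi = {res.effect_phi:.2f}")

# full network stage on a synthetic two-condition dataset
cfg = synthetic.SyntheticConfig(seed=0)
nets = semnet.run_semnet_pipeline(synthetic.gen_aut(cfg), ("OR", "DD"))
for cond, net in nets.items():
    m = semnet.compute_metrics(net)
    phi = percolation.percolate(net).integral_phi
    print(f"{cond}: n={net.n}  ASPL={m.aspl:.3f}  CC={m.cc:.3f}  "
          f"Q={m.q:.3f}  S={m.s:.3f}  percolation phi={phi:.1f}")
```

prints

```
chi2(1) = 2.267, p = 0.132, phi = 0.06
OR: n=54  ASPL=4.092  CC=0.674  Q=0.621  S=3.439  percolation phi=35.0
DD: n=54  ASPL=2.702  CC=0.728  Q=0.484  S=5.620  percolation phi=154.5
```

The McNemar line says the two conditions produced unique-response
inventories of statistically indistinguishable size (χ² = 2.27 on one
degree of freedom, a negligible φ). The network lines compare the two
synthetic arms on the same 54 matched response nodes: the "DD" arm —
generated with more homogeneous response co-occurrence — has a shorter
average path, higher small-worldness and a much larger percolation
integral, i.e. a more integrated and more robust semantic network, which
is the direction of effect the planted condition contrast encodes.

## Command line

```bash
cogflex simulate --seed 1 --out data/           # synthetic CSV inputs
cogflex run --seed 1 --out results/             # all five stages
cogflex run --input-dir data/ --out results/    # same, on your own CSVs
cogflex semnet data/aut.csv                     # just the network stage
cogflex dcm-fit data/stroop.csv --participant p000 --condition DD
cogflex traj data/trajectories.csv data/trajectory_meta.csv
```

Input schemas (CSV): responses `(participant_id, condition, prompt,
response)`; Stroop `(participant_id, condition, trial, congruent,
correct, rt_ms)`; trajectories `(trial_id, t_ms, x, y)` plus a trial
metadata table; ratings `(participant_id, condition, item, rating)` with
ratings in [0, 1]. `cogflex validate <dir>` checks them.

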