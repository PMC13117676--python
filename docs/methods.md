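# Methods

## Model and assumptions

Branch selection of a confined single-cell train at a symmetric
T-junction is modelled as a two-state first-order Markov chain over the
branch labels.  The same-branch transition probability is
`P_jj = p + α`, where `p` is the baseline in the absence of interaction
and `α` the effective leader–follower coupling (positive: attraction,
negative: repulsion), constrained to `-p ≤ α ≤ 1 - p`.  The front cell's
choice is uniform over the two branches; this is justified empirically by
the front-cell symmetry check (`front_choice_symmetry`, an exact
two-sided binomial test of the leaders' absolute left/right choices
against 0.5) and is immaterial to run-length statistics, which only see
same/opposite structure.

Assumptions worth keeping in mind:

- **First-order dependence.**  Each choice depends only on the
  immediately preceding cell.  Higher-order memory, delayed responses or
  collective effects are outside the model.
- **Stationarity within a group.**  `α` is constant within each analysed
  group of clusters.  Position dependence is handled by grouping clusters
  by order (1 = front cluster), not by a parametric decay model.
- **Symmetric junction.**  A single scalar `p` (default 0.5) describes
  both branches.  Branch-identity-dependent baselines (geometric bias)
  are not modelled; `p` can be set to a calibrated value if a junction is
  known to be biased.
- **Effective parameter.**  `α` absorbs every mechanism that correlates
  successive choices — mechanical or biochemical coupling, shape-mediated
  occlusion, transient occupancy effects.  The method measures the
  strength and range of the correlation, not its mechanism.

Under the chain, run lengths (cluster sizes) are geometric,
`P(n) = P_jj^(n-1)(1 - P_jj)` with mean `1/(1 - P_jj)`, giving two
algebraically identical estimators: mean-based
(`P̂_jj = 1 - 1/⟨n⟩_obs`) and maximum likelihood
(`P̂_jj = Σ(n_i-1)/Σ n_i`).  Both are exposed; their identity is enforced
by tests.

## Estimation, uncertainty and testing

- **Bootstrap** (`bootstrap_estimate` / `fit(bootstrap=B)`): the M
  observed cluster sizes are resampled with replacement B times
  (default 10,000); the SE is the SD of the resampled α̂ and the CI is
  the percentile interval (default 95%).  The resampling unit is the
  individual cluster.  Percentile intervals inherit the estimator's
  range `[-p, 1-p)`; samples dominated by singleton runs therefore
  produce lower limits of exactly `-p` (at p = 0.5, the recurring
  `-0.500` lower bounds).  A clustered (train-level) bootstrap is not
  implemented.
- **Likelihood-ratio test** (`lrt_parametric_bootstrap` /
  `results.lrt()`): the statistic is the standard deviance
  `Λ = 2 [log L(P̂_jj) - log L(p)]`, floored at 0.  Its null
  distribution is built parametrically: B replicate samples of M runs
  are drawn from the geometric null with `P_jj = p` and the p-value is
  `(1 + #{Λ_b ≥ Λ_obs}) / (B + 1)` (add-one convention, so the
  resolution floor is `1/(B+1)`; resolving p-values near 1e-4 needs
  B ≳ 1e5).  Because the null distribution is simulated, any fixed
  monotone form of Λ gives the same p-values; the deviance is used
  because it is standard.
- **Censoring.**  The final run of every train is censored (terminated
  by the train end, not by an opposite choice).  The default policy
  (`complete`) counts censored runs at their observed length — this is
  the convention under which the mean-based arithmetic reproduces the
  reported group estimates.  `drop_censored` removes them; a
  censoring-aware likelihood (censored runs contribute only the survival
  factor `P_jj^(n-1)`) is available through `log_likelihood(...,
  censored=...)` but is not the default.

## Finite-train effects

Two exact finite-train tools quantify what truncation does to the
statistics: `truncated_run_length_pmf` (the front-cluster law in an
N-cell train, with the geometric tail absorbed at n = N) and
`enumerate_null`, which enumerates all `2^(N-1)` same/opposite patterns
exactly (limit N ≤ 24; ~8M patterns in seconds on one CPU; longer trains
go through the simulator).  The pooled pmf uses the ratio of expected
cluster counts, matching how clusters are pooled across trains.

One consequence the tests document: in short trains, both keeping and
dropping censored runs bias run-length statistics slightly (dropping
selects against long runs; keeping shortens the last one).  The bias is
O(1/N_train) — about −0.01 on α̂ for pooled rear clusters of 20-cell
trains at α = 0 — and is negligible for front clusters at p = 0.5
(truncation requires a run of length N) and for long simulated trains.
Parameter-recovery checks therefore use long trains and non-censored
runs; experimental-scale analyses inherit whatever censoring the data
contain, which is why the complete policy mirrors the reported
arithmetic.

## Simulator and synthetic scenarios

`simulate_train` draws the front label uniformly and each follower with
probability `P_jj`; `simulate_train_nonstationary` lets α depend on the
cluster order of the predecessor at generation time (the "interface"
convention: the coupling in force at a transition is that of the cluster
the leading cell belongs to), with the last α reused beyond the list.
One seeded `numpy` Generator per ensemble is consumed train by train, so
ensembles are bit-reproducible.

Built-in scenarios generate branch tables for the pipeline:

- `null` — α = 0, 1000 trains × 20 cells: the independence baseline.
- `ms1_like` — α by order (−0.405, −0.313), 1000 × 20: uniformly
  repulsive, endothelial-like trains.
- `mdck_like` — α by order (+0.083, −0.206, −0.357, −0.409), 5000 × 20:
  weak attraction at the leader interface decaying to repulsion,
  epithelial-like trains.

The default simulated-study size (20 trials × 20 cells) matches the
validation ensembles; scenario profiles take the reported group
estimates as their generating values.  The generator emulates the
same/opposite decision structure only: it does not model junction dwell
times, cell shape or deformation, annotation error, or train-to-train
heterogeneity in α.  Passing recovery tests therefore shows the
inference is correct *for the model*, not that real trains are
first-order Markovian.

## Numerical conventions

- `0·log 0 = 0` in the likelihood, so `P_jj = 0` is admissible iff every
  run is a singleton; otherwise the log-likelihood is −∞ (returned, not
  raised).  `P_jj = 1` is rejected (infinite runs).
- Empty cluster groups raise (`EmptyGroupError`) rather than returning
  M = 0 samples, since every estimator divides by M.
- Across-trial SDs use the sample (n−1) denominator, reported as 0 for a
  single trial.
- Reports round to 3 decimals; the JSON companion keeps full precision
  plus B, seeds and policies.
- Branch tokens (`L/R`, `Up/Down`, `0/1`, case-insensitive) map onto an
  abstract binary alphabet; absolute orientation is only required by the
  front-cell symmetry check.

## Test problem sizes

Simulation-backed checks use sizes chosen to make Monte Carlo error
comfortably smaller than the tolerance being asserted: transition
frequencies from ~1.2e5 transitions; pooled recovery from ≥2e4
non-censored runs per α on 250-cell trains; order-resolved recovery from
5000 20-cell trains; LRT calibration from 2000 repetitions of M = 19
with B = 999 (a vectorised null makes this a few seconds); run-length
goodness of fit from 1000-cell trains where edge effects are negligible.

## Limitations

Beyond the model assumptions above: no train-level (clustered) bootstrap
or hierarchical modelling of between-train variability; no parametric
model of α's decay with order (range is read off the order-resolved
estimates); no multi-way junctions; no image/tracking ingestion — the
package starts from annotated branch tables.
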