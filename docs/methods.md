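# Methods

## The synthesis model

`synthtrial` generates synthetic patient data by *sequential conditional
synthesis*: the joint distribution of the table is factorised along a
visit sequence, `p(x1) p(x2|x1) p(x3|x1,x2) …`, and each conditional is
approximated by a fitted tree with leaf-donor sampling.

* The **visit sequence** is: covariates in schema order (configurable via
  the schema's `visit_order`), then `pfs_event`, `pfs_time`, `os_event`,
  `os_time`.  Event flags precede their times so that a synthesized time
  is conditioned on its censoring status, and endpoints come last so they
  condition on every covariate.
* The **first variable** has no predecessors; it is drawn uniformly with
  replacement from its observed values (a bootstrap of the marginal).
* Every **later variable** is modelled on all previously visited
  variables by a CART tree (regression tree for continuous/integer
  variables, classification tree for categoricals; event flags are always
  treated as categorical) or, in the RF variant, by an ensemble of
  `n_trees` trees each grown on a bootstrap resample with random feature
  subsetting.  Each leaf stores the *raw observed values* of its training
  donors.  To synthesize, the partially built record is routed to a leaf
  (RF: in a tree chosen uniformly at random per record) and one donor is
  drawn uniformly.  No kernel smoothing is applied, so every synthetic
  value occurs somewhere in the training data (donor closure).
* **Constraints.**  Time-to-event logic requires `pfs_time > 0`,
  `os_time > 0` and `pfs_time ≤ os_time` (progression cannot follow
  death; equality is legal).  A completed record violating any rule is
  discarded wholesale and regenerated with fresh randomness; after
  `max_rounds` (default 1000) regeneration rounds the engine fails loudly
  with the dominant violated rule and the observed rejection rate rather
  than returning a short table.  The output always has exactly the
  requested number of records.
* **Seeding protocol.**  A study draws one list of distinct 31-bit seeds
  from the master seed with the Mersenne-Twister algorithm and reuses the
  identical list for every generator, so methods are compared on matched
  randomness.  Synthesis itself also uses MT19937, making every replicate
  bit-reproducible from `(training data, method, seed)`.  Models are fit
  once per method — fitting is deterministic given the training data (RF
  bootstraps use a fixed `fit_seed` hyperparameter) — and only sampling
  consumes the replicate seed.

Tree induction is delegated to scikit-learn; categorical predictors enter
the trees as integer level codes.  Hyperparameter defaults are
`min_leaf = 5`, no depth limit, impurity splitting (variance / Gini);
RF adds `n_trees = 10` and `√p` feature subsetting.  These mirror the
customary defaults of tree-based synthesis tools; `min_leaf` is the
knob that trades fidelity (small leaves reproduce the joint distribution,
to the point of near-copying) against generalisation and disclosure risk.

Other generators can be plugged in through the registry: anything with
`fit(table)` and `sample(n, seed) -> TrialTable` participates in a study
on equal terms (this is where a Bayesian-network or deep generative model
would attach).  Two references are built in: `resample` (whole-row
bootstrap, constraint-satisfying by construction, behaves like a
bootstrap of the empirical distribution) and `scaled` (a deliberately
misspecified negative control that multiplies both endpoint times by 3).

## The evaluation battery

For each replicate and endpoint the package computes:

* **Kaplan-Meier product-limit curve** `S(t) = Π (1 − d_i/n_i)` over the
  distinct event times, ties processing events before censorings, with
  Greenwood variance `S(t)² Σ d_j / (n_j (n_j − d_j))`.
* **Median survival time (MST)**: the smallest event time with
  `S(t) ≤ 0.5` (undefined when the curve never reaches 0.5 — a synthetic
  replicate whose median is undefined is *not* counted as covered).
  Its CI inverts the transformed pointwise band (the Brookmeyer-Crowley
  construction): each bound is the first event time at which the
  corresponding band limit falls to 0.5.  The default transform is the
  complementary log-log of `S` with Greenwood variance, which keeps the
  band inside [0, 1]; `plain` and `log` transforms are available because
  coverage percentages are sensitive to this choice.
* **Hazard-ratio distance.**  A two-group Cox proportional-hazards model
  is fitted on the pooled actual + synthetic sample with a single group
  indicator (synthetic = 1, actual = reference; the direction is
  configurable since the distance is asymmetric under inversion), Efron
  handling of ties — donor sampling creates many — and Newton iteration
  to gradient norm ≤ 1e-8.  A converged |β̂| > 15 is reported as complete
  separation rather than returned, since the gradient decays to zero
  along a monotone partial likelihood.  The similarity score is
  `HRD = 1 − |HR − 1|`: 1 iff the hazards coincide, negative once
  HR > 2.
* **Coverage**: the proportion of replicate synthetic medians falling
  inside the actual median's two-sided 95% CI, bounds inclusive (medians
  are conventionally reported as whole days).  Replicates that exhaust
  the regeneration budget are excluded from the denominator and counted
  separately — never silently dropped.
* **Best/worst cases** per method and endpoint are the replicates with
  the highest and lowest HRD (ties resolved toward the smaller replicate
  index); each is re-synthesized deterministically from its stored seed
  and compared to the actual arm with the **log-rank test**
  (hypergeometric variance, 1 df, no multiplicity adjustment).

Synthesized event flags are used as-is in the synthetic KM/Cox/log-rank
computations: the engine synthesizes censoring indicators jointly with
times, so discarding them would misstate the synthetic risk sets.

## The trial simulator

Real control-arm datasets of this kind live behind access-restricted
repositories, so the test bed is a simulator whose truth is known:

* progression time `T_prog ~ Weibull(k_p, λ_p)` with covariate effects on
  the log hazard, entered in the accelerated-scale form
  `λ_p · exp(−βᵀx / k_p)` (exactly equivalent to proportional hazards for
  Weibull, and it keeps a closed-form per-subject median);
* death `T_death = T_prog + U`, `U ~ Weibull(k_d, λ_d)` — the ordering
  `PFS ≤ OS` holds by construction, and OS is never degenerate at PFS;
* one censoring time per subject, `C = min(admin, Exp(dropout))`,
  censors both endpoints (the subject leaves the study), preserving the
  ordering after censoring.

The reference scenario (`default_sim_config`) has 232 subjects — the
size of a small phase-III control arm, where synthesis is hardest and
most interesting — four mixed covariates (age, sex, ECOG performance
status, prior therapy) with moderate hazard effects, `k_p = 1.3`,
`λ_p = 200 d`, `k_d = 1.2`, `λ_d = 240 d`, administrative censoring at
900 d (~1.5× the true OS median) and dropout hazard 5e-4 per day,
yielding ≈9% censored PFS and ≈18% censored OS.  True marginal medians
come from the Weibull closed form `λ (ln 2)^{1/k}` when PFS is
covariate-free, otherwise from ≥10⁶ Monte-Carlo latent draws under a
fixed oracle seed (standard error from a central quantile-difference
density estimate).

What the simulator does *not* emulate: tumour-assessment interval
censoring (progression is observed continuously), competing risks other
than death, recruitment dynamics, and covariate missingness patterns of
real case-report forms.  Passing tests therefore demonstrate that the
synthesis and evaluation machinery is correct and calibrated under a
realistic small-trial regime — not that any generator reproduces the
idiosyncrasies of a particular real trial.

## Numerical and design choices

* Times are real-valued days throughout; no date arithmetic.
* CSV interchange writes floats with `repr` (shortest exact decimal) and
  reads with round-trip parsing, so write→read is value-identical and
  repeated writes are byte-identical.
* Missing categorical covariates become the sentinel level `"missing"`
  (a category the trees can condition on); missing continuous covariates
  are rejected — imputation is out of scope.
* A variable with a single observed value is fitted as a constant donor
  pool with a warning instead of crashing the tree fitter.
* Study sizes: the default test and acceptance runs use 100 replicates
  of the 232-subject scenario, 1000 replicates for the synthesis
  constraint sweep and for the calibration studies (median-CI coverage,
  log-rank size).  Full-scale studies (1000 replicates per method) run
  through the same code path via `RunConfig.n_replicates` and are
  resumable from the per-replicate CSV checkpoint.

## Known limitations

* Donor closure means the synthesizer cannot extrapolate beyond observed
  values; with very small training arms, CART leaves can nearly copy
  records (good similarity statistics, weak privacy).  No
  disclosure-risk mechanism is included.
* The Cox model used for HRD is the unadjusted two-group model; the HRD
  summarises marginal survival similarity only, not joint
  covariate-outcome fidelity.
* The rejection loop assumes the fitted conditionals give the constraint
  set non-negligible mass; a severely inconsistent training table
  surfaces as a `SynthesisError` with diagnostics rather than a repair.
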