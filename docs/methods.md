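# Methods

## The model

`mthet` studies how mitochondrial DNA (mtDNA) heteroplasmy — the
fraction *h* of a cell's mtDNA molecules carrying a pathogenic variant —
is transmitted through the germ line, and whether that transmission is
purely neutral drift or shaped by selection.

### Replication in non-dividing oocytes

A developing oocyte does not divide, but its mtDNA content grows from a
few hundred molecules in primordial follicles to ~10⁵ at the antral
stage.  The simulator (`oocyte_sim`) models this as a discrete-time
birth process on the integer pair (m, w) of mutant and wild-type copy
numbers:

1. at each iteration a subset of at most R₀ molecules replicates
   (limited replication machinery); the number of mutant slots is drawn
   `Binomial(min(R₀, m+w), h)` and capped at the available molecules,
   with excess slots reassigned to the other type;
2. each slot yields one new copy with per-type birth probability λ_m
   (mutant) or λ_w (wild type);
3. the run stops when m + w ≥ N_final, or is flagged incomplete at
   t_max iterations.

Six hypotheses H = 0..5 modulate the mutant rate.  *Positive selection*
means λ_m is free (typically λ_m > λ_w); models without it force
λ_m = λ_w at construction.  *Negative selection* sets the mutant birth
probability to zero for any iteration in which h exceeds a threshold:
h_th for H ∈ {0,1,2}, never for H ∈ {3,4}, and for H = 5 a threshold
that depends on the absolute wild-type count — h_th1 while w < w_th,
h_th2 (> h_th1) once w ≥ w_th.  H = 5 captures the idea that a cell can
tolerate a high mutant load only when it still holds enough functional
genomes in absolute terms.

Key structural choices, made where the model family itself leaves them
open:

* **Slot allocation is stochastic** (binomial in h), not deterministic
  rounding: it is unbiased in expectation, consistent with the rest of
  the model, and degenerates correctly at h ∈ {0, 1}.
* **Birth law**: λ is a per-slot Bernoulli probability per iteration, so
  λ ∈ [0, 1] and one slot yields at most one new copy.
* **No degradation**: the process is pure birth; copy number is
  non-decreasing.  Real oocytes also turn mtDNA over; this is a known
  limitation, and any effect of turnover is absorbed into the effective
  rates.
* **Time is abstract**: iterations have no physical unit; the switch
  time T for H ∈ {2,3} is an iteration index.  Default t_max = 5000.
* **Termination by copy number** (default N_final = 1.41 × 10⁵, the
  antral mean) rather than by duration, because copy number is the
  measurable endpoint.
* **Stage snapshots** are taken at the first crossing of copy-number
  milestones (primary 3 × 10³, secondary 2 × 10⁴, antral N_final;
  configurable, each capped at N_final).  Primordial is the initial
  state.
* A replicated molecule does not re-enter the replicating subset within
  the same iteration.
* Wild type may go extinct (h fixates at 1); no hard ceiling is
  imposed — any empirical ceiling must emerge from the selection
  parameters.

The per-cell inner loop is JIT-compiled with numba.  Each cell receives
an independent 31-bit sub-seed drawn from the caller's generator, making
cohorts reproducible and order-independent.  A pure-numpy `step`
mirrors one kernel iteration for direct testing; the equivalence of the
two paths is covered by a distributional test against a per-molecule
Bernoulli oracle.

### Segregation statistics

For a cell (or pup) with heteroplasmy h and maternal reference h₀:

* shift: h − h₀;
* transformed shift: h′ = ln(h(1−h₀)/(h₀(1−h))) = logit(h) − logit(h₀),
  antisymmetric, sign-faithful, and comparable across mothers with
  different baselines;
* normalized variance: V′(h) = Var(h)/(μ(1−μ)), 0 with no segregation,
  1 at complete fixation.

V′ uses the population variance (divisor n) by default so that the
fixation bound V′ ≤ 1 holds exactly; the sample-variance convention is
available via `ddof=1`.  Transformed shifts are undefined at h ∈ {0,1};
the default policy raises, with an opt-in clamp at ε = 10⁻⁴ (used
internally where fixated cells are unavoidable, e.g. in ABC summary
statistics).  Heteroplasmy is handled as a fraction everywhere inside
the package; percent input is detected (values > 1) and converted at
the I/O boundary only.

Transmission analysis is ordinary least squares of offspring h on
maternal h₀ with 95% confidence bands (statsmodels), plus a per-mother
mean-shift table with SEMs.  A slope below 1 with positive intercept is
reported as the selection signature: shifts are positive below the
crossing point h₀* = intercept/(1 − slope) and negative above it.
Stage comparisons use one- and two-sample t tests with Bonferroni
correction (adjusted p = min(1, raw × corrections); the correction
count defaults to the number of tests performed).  Litter structure is
deliberately not modelled (plain regression, no mixed effects).

### Kimura distribution

Pure neutral drift from initial frequency p yields the classical
diffusion solution: point masses P0, P1 at the fixation boundaries and
a continuous density expressed as a Gegenbauer-polynomial series; drift
intensity is parameterised by b ∈ [0,1], with mean p for all b and
variance p(1−p)(1−b).  Implementation notes:

* the basis `F_i(x) = ₂F₁(1−i, i+2; 2; x)` is evaluated through the
  Jacobi-polynomial three-term recurrence (validated against
  `scipy.special.eval_jacobi`);
* series terms are added until the sup-norm bound of the next term
  falls below 10⁻¹⁰ (cap 500 terms; exceeding the cap raises a
  convergence error).  b = 1 is special-cased as a point mass at p;
* moments and normalization are computed by 256-node Gauss–Legendre
  quadrature, which is exact for the truncated polynomial series, so
  the identity residuals measure pure truncation error (≈ 10⁻¹⁴ in
  practice);
* the CDF for sampling and KS testing lives on a 2048-point uniform
  grid; the interior integral is rescaled to close the quadrature
  defect so the CDF spans exactly [P0, 1 − P1].  Grid error is far
  below the statistical resolution at the sample sizes involved;
* fitting is by moments: p̂ = mean, b̂ = 1 − V′ clamped to [0, 1].
  Maximum likelihood over the mixed discrete/continuous density was
  considered and not adopted — the moment fit is the established
  practice for heteroplasmy data and is what the b̂ = 1 − V′ identity
  requires;
* goodness of fit uses the exact mixed-CDF KS statistic (both
  one-sided deviations evaluated at every observation and at the two
  atoms) with a **Monte-Carlo p-value only**: the distribution has
  atoms and the parameters are estimated, so the asymptotic KS null is
  invalid.  With fitted parameters the null replicates re-fit per
  replicate (parametric bootstrap); both refit modes are exposed
  because the correct choice depends on whether parameters were known
  a priori.

### ABC rejection and model selection

Particles draw H uniformly from {0..5} and parameters from weakly
informative priors: λ_w, λ_m ~ U(0.05, 1) (equal for H ∈ {1,4});
R₀ log-uniform on [10, 10³]; thresholds ~ U(0.2, 0.99) with
h_th1 < h_th2 enforced by rejection; w_th log-uniform on [10², 10⁴];
T uniform over the iteration range.  Each particle simulates a cohort
from the observed primordial states.  The stopping copy number is
cell-specific: antral copy number varies between cells for reasons the
selection hypotheses do not describe, so per-cell endpoints are drawn
once from a log-normal law matched to the observed antral log₁₀
mean/SD and shared by every particle (common random numbers keep the
particle comparison sharp).  Without this, no particle can reproduce
the observed antral copy-number dispersion and tight-threshold model
selection degenerates into rewarding slow-growth parametrizations whose
incomplete cells fake that dispersion.  Each cohort is summarised per
stage group
(primordial, growing, antral) by: mean transformed shift (relative to
each cell's initial heteroplasmy), V′, and mean and SD of log₁₀ copy
number.  The distance is Euclidean after per-component standardization
by the SD over a 1000-particle pilot pool (the first particles of the
run); components that do not vary across particles — the primordial
summaries, fixed by the starting states — carry no information about
the parameters and are excluded.  Acceptance thresholds are the
{5%, 1%, 0.5%, 0.1%} quantiles of the pooled distance distribution;
per-model support at each threshold is the accepted share.  Posterior
summaries (mean, SD, equal-tailed credible interval) are computed over
accepted particles, optionally restricted to one model, and require at
least 10 acceptances.  For a parameter posterior *conditional on a
model*, the recommended threshold is a quantile of that model's own
distance distribution (e.g. the best 5% of H = 5 particles): the
cross-model thresholds used for model selection can leave a model with
few — or zero — acceptances even when its parameters are well
identified within it.  Plain rejection only — no SMC, regression
adjustment, or neural estimation.

### Meiotic partition model

Spermatogenesis partitions a 4N spermatocyte's mitochondrial pool over
two divisions with no net mtDNA replication.  Each division is one
symmetric binomial split, m′ ~ Binomial(m, ½), w′ ~ Binomial(w, ½):
one step predicts 2C cells, two steps 1C.  Starting states are drawn
from a Gaussian KDE fitted to measured 4N cells in log₁₀(1 + count)
coordinates (copy numbers span orders of magnitude), back-transformed,
rounded and truncated at zero; cells drawn empty are redrawn and
counted.  When the 4N data are degenerate (a zero-variance or
perfectly correlated dimension makes the full-covariance KDE singular)
a product-kernel fallback with Scott's factor per dimension is used,
keeping exact dimensions exact.  Partitioning preserves mean
heteroplasmy up to an O(1/N) ratio bias and strictly inflates V′ at
each step — the neutral vegetative-segregation prediction against which
observed sperm data can be compared.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
so the whole pipeline is testable with no external input:

* maternal h₀ ~ U(0.2, 0.8) by default; per-mother primordial cells get
  h ~ Kimura(h₀, b) with bottleneck parameter b = 0.98 (primordial
  V′ ≈ 0.02, in the range reported for heteroplasmic mice) and
  copy numbers from a log-normal law with natural-scale mean 347 and
  SD 355.8;
* cells are forward-simulated under a chosen generating model to
  per-cell antral targets drawn log-normally (mean 1.41 × 10⁵,
  SD 4.38 × 10⁴); intermediate stages are simulated to proportionally
  scaled milestones;
* the transmission generator defaults to 42 mothers and 1167 pups
  (spread as evenly as possible), one fully developed cell per pup,
  with maternal ages ~ U(2, 12) months;
* sperm tables draw 4N totals log-normally (mean 772, SD 281.35) with
  binomial mutant counts, then apply the partition law for 2N and 1N —
  so the meiosis model's neutral prediction is exactly correct on this
  data by construction;
* measurement noise is additive Gaussian on the fraction scale
  (SD 0.015, truncated to [0, 1]), a plausible assay error for
  pyrosequencing-style quantification.

What the generator does **not** emulate: litter structure, age
structure of mothers beyond a uniform draw, assay-specific error shapes
(it is symmetric and homoscedastic), mtDNA turnover, or any coupling
between copy number and heteroplasmy beyond what the replication model
itself produces.  Passing tests on this data therefore demonstrate the
correctness and calibration of the *methods*, not biological claims
about any particular dataset.

## Problem sizes and numerical choices

The inference-level tests and the acceptance script run under scaled
study conditions chosen once: antral endpoint N_final = 5000 copies
(instead of 1.41 × 10⁵), t_max = 1500, cohorts of 16 primordial cells,
6 mothers × 8 cells per stage for observed datasets, 2000 particles per
ABC run, 20 replicates for coverage checks, and 500 datasets × 400
Monte-Carlo replicates for the KS calibration.  These sizes keep every
cell through hundreds of replication iterations (so the drift/selection
dynamics are in the same regime as the full-scale model) while keeping
a complete run in minutes.  Simulator checks that are cheap at full
scale (the drift martingale at N_final = 10⁴ with 2000 cells, the
suppression rule) run unscaled.

Degenerate inputs are handled by explicit errors rather than silent
repair: extinct cells, boundary heteroplasmies in the transformed
shift, degenerate means in V′ and the Kimura fit, rank-deficient
regressions, and insufficient ABC acceptances all raise typed
exceptions from `mthet.errors`.

## Known limitations

* The replication model is pure birth; degradation/turnover and any
  physical time calibration are out of scope.
* ABC summary statistics, priors and the distance are package choices;
  inference quality on real data depends on them in the usual ABC way.
* The Kimura KS test's Monte-Carlo p-value has resolution 1/(n_mc + 1).
* The moment estimator b̂ = 1 − V′ is biased upward at small n when V′
  is clamped at the [0, 1] boundary.
* The meiosis KDE bandwidth (Scott) and log-coordinates are pragmatic
  defaults; heavily multimodal 4N data may need a custom `bw_method`.
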