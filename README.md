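# mthet

Mitochondrial DNA (mtDNA) heteroplasmy — the fraction *h* of a cell's
mtDNA molecules carrying a variant — is reshaped twice in the germ
line: a prenatal copy-number bottleneck spreads heteroplasmy between
offspring, and selection during oocyte growth can push it up or down.
`mthet` is a toolkit for quantifying both effects from single-cell
measurements.  It is aimed at researchers analysing heteroplasmy
transmission in model organisms (or human pedigrees) who need a tested,
reproducible implementation of:

* a **stochastic simulator** of mutant/wild-type mtDNA replication in
  non-dividing oocytes: per iteration, at most R₀ molecules replicate
  (slots drawn binomially by heteroplasmy) with per-type birth
  probabilities λ_m, λ_w, under six selection hypotheses H = 0..5 —
  from pure neutral drift (H = 4) to a replicative advantage combined
  with copy-number-dependent purifying selection (H = 5: mutant
  replication stops above h_th1 while the wild-type count w < w_th,
  above h_th2 otherwise);
* **ABC rejection inference**: model selection over H = 0..5 and
  posterior summaries for (λ_m, λ_w, R₀, h_th, T, h_th1, h_th2, w_th)
  from per-stage summary statistics of single-oocyte data;
* **segregation statistics**: heteroplasmy shift h − h₀, transformed
  shift h′ = ln(h(1−h₀)/(h₀(1−h))), normalized variance
  V′ = Var(h)/(μ(1−μ)), mother→offspring transmission regression,
  maternal-age regression, and Bonferroni-corrected stage comparisons;
* the **Kimura distribution** of heteroplasmy under pure drift
  (fixation masses + Gegenbauer series density), with moment fitting
  (p̂ = mean, b̂ = 1 − V′) and a Monte-Carlo Kolmogorov–Smirnov
  goodness-of-fit test that handles the atoms and estimated parameters
  correctly;
* a **meiotic partition model** for sperm data: kernel density over
  measured 4N spermatocytes in copy-number space, one/two symmetric
  binomial splits predicting 2C/1C heteroplasmy;
* a **synthetic-data generator** reproducing the statistical structure
  of such studies end to end (bottlenecked primordial oocytes,
  stage-wise copy-number growth, mother/pup tables, sperm ploidy
  series), so the whole pipeline is testable without any dataset.

## Worked example

```python
import numpy as np
from mthet.synthetic_data import SynthConfig, default_selection_params, \
    gen_transmission_table
from mthet.het_stats import fit_transmission

rng = np.random.default_rng(61)
cfg = SynthConfig(n_mothers=20, n_pups=300, h0_lo=0.15, h0_hi=0.85,
                  antral_mean=5_000.0, antral_sd=1_500.0,
                  sim_params=default_selection_params(N_final=5_000,
                                                      t_max=1_500))
pairs = gen_transmission_table(cfg, rng)
fit = fit_transmission(pairs)
r = fit.regression
print(f"slope     = {r.slope:.3f}  (95% CI {r.slope_ci[0]:.3f}..{r.slope_ci[1]:.3f})")
print(f"intercept = {r.intercept:.3f}")
print(f"selection signature: {fit.selection_signature}, "
      f"shift changes sign at h0 = {fit.crossing_h0:.3f}")
```

prints

```
slope     = 0.319  (95% CI 0.275..0.362)
intercept = 0.429
selection signature: True, shift changes sign at h0 = 0.630
```

300 pups from 20 mothers were simulated under the copy-number-dependent
selection model (mutant birth rate 1.5× wild type, tolerance thresholds
0.5/0.8 around w_th = 500).  A slope well below 1 with a positive
intercept is the transmission signature of that selection: mothers
below h₀ ≈ 0.63 hand *higher* heteroplasmy to their pups, mothers above
it hand down *lower* values.  Under the neutral model the same pipeline
returns a slope statistically indistinguishable from 1.

The same machinery is available from the shell:

```bash
mthet synth --seed 1 --out-dir data/          # generate all three tables
mthet stats --pairs data/pairs.csv            # transmission regression
mthet kimura ks --data primordial_h.txt       # Kimura goodness of fit
mthet abc --cells data/oocytes.csv --seed 1   # model selection
mthet meiosis --sperm data/sperm.csv          # 2C/1C partition prediction
```

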