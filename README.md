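# shapekf

Denoising of multi-replicate RNA SHAPE reactivity profiles under a
log-normal measurement-noise model.

SHAPE (Selective 2′-Hydroxyl Acylation analyzed by Primer Extension)
chemical probing measures per-nucleotide RNA backbone flexibility; the
resulting reactivity profile informs secondary-structure prediction.
Replicate experiments disagree, and the disagreement is multiplicative:
the between-replicate standard deviation scales roughly proportionally
with the mean, and the reactivity distribution itself is near-Gaussian
only after a log transform. Plain data-domain averaging is therefore the
wrong combiner — under multiplicative noise it is biased upward by a
factor e^{σ²/2}.

`shapekf` is for experimentalists and analysts who have two or more
normalized SHAPE replicates of the same RNA and want a single profile
that best recovers the underlying reactivities.

## Model

Each nucleotide *m* has a fixed true reactivity *s_m* with log reactivity
*l_m* = log *s_m*. Replicate *i* observes

  *l_mi* = *l_m* + *w_mi*,  *w_mi* ~ N(0, σ_wm)   (additive Gaussian in the log domain)

equivalently *r_mi* = *s_m* · e^{w_mi} in the data domain. Three combiners
are provided:

- **average** — arithmetic mean of *r_mi* (the conventional approach;
  biased under this model);
- **log-average** — mean of *l_mi*, exponentiated back: the geometric mean;
- **kalman** — a scalar Kalman filter run per nucleotide in the log
  domain. The state is constant across replicates, so the filter reduces
  to sequential Bayesian updating of a Gaussian prior N(μ₀, σ₀) on log
  reactivities, with the measurement-noise variance estimated by the
  sample variance of the log measurements. The final estimate is the
  conjugate-normal posterior mean

    k = (μ₀/σ₀² + N·l̄/σ̂_w²) / (1/σ₀² + N/σ̂_w²),

  a precision-weighted shrinkage of the log-average toward the prior.
  The shipped default prior is N(−1.74, 1.52), a Gaussian fit to a
  database-scale distribution of log-transformed normalized reactivities.

The filter helps most with few replicates (N ≤ 3) and high noise
(σ_w ≥ 1), where the prior carries real information; with many replicates
or low noise it coincides with the log-average.

Around the combiners the package implements the full workflow:
background-distribution replacement of non-positive reactivities (so
profiles become log-transformable), box-plot outlier detection and
top-band (2%-scale) normalization, replicate simulation under calibrated
noise regimes (low σ ∈ (0, 0.5), medium (0.5, 1), high (1, 1.5)),
log-domain RMS error, base-pair MCC between secondary structures
(CT / dot-bracket), and the mean–SD log-log heteroskedasticity diagnostic.

## Worked example

```python
import numpy as np
from shapekf import (
    DEFAULT_PRIOR, NoiseRegime, generate_ground_truth, simulate_replicates,
    average_profile, log_average_profile, kalman_profile,
    rms_error, mean_sd_loglog_fit,
)
from shapekf.preprocess import to_log_domain

rng = np.random.default_rng(42)
truth = generate_ground_truth(300, DEFAULT_PRIOR, rng)   # synthetic RNA, 300 nt
reps = simulate_replicates(truth, 3, "high", rng)        # 3 noisy replicates

tl = to_log_domain(truth)
for name, est in [("average", average_profile(reps)),
                  ("log-average", log_average_profile(reps)),
                  ("kalman", kalman_profile(reps))]:
    print(f"{name:12s} RMS(log) = {rms_error(to_log_domain(est), tl):.3f}")

fit = mean_sd_loglog_fit(simulate_replicates(truth, 5, NoiseRegime(0, 1.5), rng))
print(f"mean-SD log-log slope = {fit.slope:.3f} over {fit.n_points} nucleotides")
```

prints

```
average      RMS(log) = 0.917
log-average  RMS(log) = 0.762
kalman       RMS(log) = 0.669
mean-SD log-log slope = 1.135 over 300 nucleotides
```

With 3 high-noise replicates the data-domain average is worst (its
multiplicative bias shows up as log-domain error), the geometric mean
removes the bias, and the Kalman filter improves further by borrowing
strength from the prior. The slope near 1 confirms the simulated noise
reproduces the mean-proportional SD seen in real replicate sets.

The same workflow is available from the shell:

```sh
shapekf simulate --truth truth.shape -N 3 --regime high --seed 17 --out-prefix rep
shapekf denoise --method kalman rep_1.shape rep_2.shape rep_3.shape -o kf.shape
shapekf evaluate rms --truth truth.shape --est kf.shape
shapekf grid --seed 1 --n-nucleotides 10000 --out-dir grid_results
```

Profiles are two-column text files (1-based position, reactivity, −999 =
missing). `shapekf grid` writes tidy TSV tables for the replicate-count
sweep, the RMS heat maps over (reactivity, noise SD) bins, and the
prior-sensitivity grid.

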