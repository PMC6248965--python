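# Methods

## Noise model and combiners

A nucleotide's true reactivity s_m is assumed constant across replicates.
Measurements are modelled as multiplicative: r_mi = s_m · e^{w_mi} with
w_mi ~ N(0, σ_wm) independent across replicates, i.e. additive Gaussian
noise in the log domain. This choice is motivated by two empirical
features of normalized SHAPE data: the reactivity distribution is
near-Gaussian after a log transform, and the between-replicate SD is
roughly proportional to the mean (the log(SD)–log(mean) relationship is
linear with slope ≈ 1). Under this model the data-domain arithmetic mean
is biased: E[r̄_m] = s_m · e^{σ_wm²/2}.

Log-averaging exponentiates the mean log measurement — the geometric
mean — and is the maximum-likelihood estimate of s_m under the model
without a prior.

The Kalman filter runs per nucleotide in the log domain. Because the
state is static, the predict step is the identity and the filter is
exactly sequential conjugate-Gaussian updating: initialize at the prior
(l̂₀ = μ₀, σ₀²), then for each measurement compute the gain
K_i = σ²_{i−1}/(σ²_{i−1} + σ̂_w²), update the estimate by K_i times the
innovation, and scale the variance by (1 − K_i). The per-measurement
noise variance σ̂_w² is the unbiased (N−1) sample variance of the
nucleotide's log measurements. The final estimate equals the closed-form
posterior mean, a precision-weighted convex combination of the prior
mean and the log-average; the test suite asserts this equivalence to
1e-9 on random instances, which also fixes the interpretation of the
variance recursion (it acts on variances, not SDs). The estimate is
consequently invariant to measurement order and always lies between μ₀
and the log-average.

Numerics: the gain complement 1 − K_i is computed directly as
σ̂_w²/(σ²_{i−1} + σ̂_w²); the literal subtraction loses ~4e-6 relative
accuracy through cancellation when the prior is nearly flat (σ₀ ~ 1e6).
Degenerate inputs are short-circuited at their analytic limits: a
zero-SD prior returns the prior mean with zero variance (absolute prior
certainty; gains are all 0); identical measurements (σ̂_w² = 0) return
the common value with zero variance, the σ̂_w² → 0 limit of the
posterior, avoiding a 0/0 gain. A nucleotide with a single usable
measurement has no sample variance and is emitted as missing (with a
warning) unless the caller supplies a fixed measurement SD.

## Parameters

| parameter | default | meaning |
|---|---|---|
| prior μ₀ | −1.74 | mean of the Gaussian prior on log reactivities (log units of normalized reactivity) |
| prior σ₀ | 1.52 | SD of that prior |
| background cutoff | −0.25 | truncation of the pooled negative-reactivity distribution used for replacement |
| top_fraction | 0.10 | fraction of (non-outlier) nucleotides averaged into the normalization factor |
| outlier cap | 5% (< 100 nt), 10% (≥ 100 nt) | maximum fraction of values flagged by the box-plot rule |
| noise regimes | low (0, 0.5), medium (0.5, 1), high (1, 1.5) | uniform bounds on the per-nucleotide log-domain noise SD |
| ideal-prior sweeps | μ_offset ∈ [−3, 3], σ_{m,0} ∈ [0, 5] | perturbation ranges for the prior-sensitivity study |

The default prior is a moment fit (sample mean and N−1 SD) to a
database-scale empirical distribution of log-transformed normalized
reactivities; `fit_prior` recomputes it for any user dataset.
`fit_prior` uses moment matching rather than a nonlinear Gaussian fit —
for a near-Gaussian sample the two coincide, and moments are exact and
deterministic.

## Preprocessing and normalization

Log transformation requires strictly positive profiles. Non-positive
reactivities (background over-subtraction artifacts) are replaced by the
absolute value of a draw from the empirical distribution of negative
reactivities pooled across a reference profile set, truncated at the
cutoff; replacements therefore land in (0, |cutoff|], the magnitude
range of an unreactive nucleotide. Zeros are replacement targets but
never background samples, and missing entries are never replaced. The
background distribution is sampled uniformly with replacement over the
retained empirical values — the minimal assumption; no parametric form
is imposed.

Normalization follows the model-free box-plot convention: candidates
above Q3 + 1.5·IQR are outliers (quartiles by linear interpolation
between order statistics, numpy's default "type 7"; the convention is
configurable since the literature does not fix one), capped at 5%/10% of
the non-missing count with the largest values retained (ties broken
toward the lower position). The factor is the mean of the top 10% band,
computed either excluding (default) or including the outliers — the two
variants differ only when outliers exist, and the excluding factor is
never larger. The whole profile, outliers and negatives included, is
divided by the factor; nothing is clipped. Simulated replicates are not
re-normalized by default: the noise model describes post-normalization
variation.

## The simulator and what it does not emulate

`generate_ground_truth` draws i.i.d. log reactivities from the prior
Gaussian — a synthetic stand-in for a database of real profiles that
reproduces the marginal reactivity distribution but none of the
sequence-local structure (helices produce runs of low reactivity in real
RNAs). `simulate_replicates` draws one σ_wm per nucleotide from the
regime, shared across all N replicates of that nucleotide, then adds
independent Gaussian log-noise. Nucleotide independence and
replicate-independent σ are model assumptions, not facts about real
data: passing tests demonstrate correct behavior under the model, not
that real SHAPE noise is exactly log-normal or uncorrelated along the
sequence. Read-count-level stochasticity (coverage, Poisson counting) is
below the abstraction level of this model.

A data-domain additive-Gaussian simulator (`simulate_replicates_normal`)
exists only for didactic contrast; it can produce non-positive
measurements and is never a default.

## Evaluation

RMS error is computed in the log domain over positions non-missing in
both profiles (a data-domain variant exists behind a separate function).
MCC uses the universe of all M(M−1)/2 unordered position pairs for the
true-negative count — no loop-length or base-identity restriction; TN
dominates at typical M, so the choice is immaterial to the reported
values — and returns 0 when any marginal sum is zero. The
heteroskedasticity diagnostic excludes non-positive measurements and
zero-SD nucleotides, then fits ordinary least squares of log(SD) on
log(mean). With 5 replicates the fitted slope sits slightly above 1
(typically 1.05–1.11 at 2,216 nucleotides): the sampling errors of the
per-nucleotide mean and SD are positively correlated, which biases the
OLS slope upward relative to the population value of exactly 1.

## Study scales

The simulation studies run on a synthetic database of 10⁴ nucleotides
(the scale at which RMS differences of a few percent are resolvable:
the Monte-Carlo SE of an RMS over 10⁴ points is ≈ 0.7%), the
heteroskedasticity diagnostic on 2,216 nucleotides with 5 replicates,
and the averaging-bias check on 10⁴ replicates of a single nucleotide.
`RunConfig` exposes all sizes; `shapekf grid` defaults to the same 10⁴.

## Known limitations

- The prior is global; real reactivities are structure-dependent, and a
  per-nucleotide informative prior (explored via `make_ideal_prior`)
  requires external information no experiment provides directly.
- σ̂_w² from 2–3 replicates is itself very noisy; the filter treats it
  as known, which understates posterior uncertainty at small N.
- Dot-bracket parsing is nested-only; pseudoknots must arrive as CT.
- No secondary-structure folding engine is included or invoked; MCC
  compares two given structures.
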