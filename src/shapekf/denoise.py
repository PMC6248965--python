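"""Replicate combiners: averaging, log-averaging, and per-nucleotide Kalman filtering.

Three ways to collapse N replicate measurements of a nucleotide into one
reactivity estimate:

* ``average_profile`` — arithmetic mean in the data domain. Optimal under
  additive Gaussian noise, but biased upward by a factor exp(sigma_w^2/2)
  under multiplicative (log-normal) noise.
* ``log_average_profile`` — mean of the log measurements, exponentiated
  back: the geometric mean. Unbiased for the log reactivity under the
  log-normal model.
* ``kalman_profile`` — a scalar Kalman filter run in the log domain for
  each nucleotide independently. The state (the true log reactivity) is
  constant across replicates, so the predict step is the identity and the
  filter reduces to sequential Bayesian updating of a Gaussian prior
  N(mu0, sigma0) with measurements of estimated variance sigma_w_hat^2
  (the sample variance of the log measurements). The final estimate is
  the conjugate-normal posterior mean — a shrinkage of the log-average
  toward the prior mean, weighted by relative precision.

The filter's advantage over log-averaging is largest with few replicates
and high noise, where the prior carries real information; with many
replicates or low noise the two coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from shapekf.io_formats import DomainError, ReactivityProfile
from shapekf.simulate import ReplicateSet


@dataclass(frozen=True)
class GaussianPrior:
    """Gaussian prior on log reactivities, N(mu, sigma)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("prior mean must be finite")
        if self.sigma < 0:
            raise ValueError("prior sigma must be >= 0")


#: Prior fit to a database-scale empirical distribution of log-transformed
#: normalized SHAPE reactivities.
DEFAULT_PRIOR = GaussianPrior(mu=-1.74, sigma=1.52)


@dataclass(frozen=True)
class IdealPriorSpec:
    """Perturbation of the per-nucleotide ideal prior (simulation studies only).

    The ideal prior for nucleotide m is centred on its true log reactivity
    l_m with SD 0. ``mu_offset`` shifts every prior mean away from the
    truth (loss of accuracy); ``sigma`` widens it (loss of precision).
    Offsets of interest span [-3, 3] and SDs [0, 5].
    """

    mu_offset: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("prior sigma must be >= 0")


@dataclass(frozen=True)
class KalmanState:
    """Final filter state for one nucleotide.

    ``estimate`` is the posterior mean of the log reactivity after all
    measurements; ``variance`` its posterior variance; ``gains`` the
    sequence of Kalman gains, each in [0, 1]; ``measurement_variance``
    the estimated per-measurement noise variance (sample variance of the
    log measurements).
    """

    estimate: float
    variance: float
    gains: tuple[float, ...]
    measurement_variance: float


def average_profile(reps: ReplicateSet) -> ReactivityProfile:
    """Per-nucleotide arithmetic mean across available measurements."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        means = np.nanmean(reps.measurements, axis=1)
    return ReactivityProfile(means, rna_id=reps.rna_id)


def log_average_profile(reps: ReplicateSet) -> ReactivityProfile:
    """Geometric mean per nucleotide: exp of the mean log measurement."""
    arr = reps.measurements
    if np.any(~np.isnan(arr) & (arr <= 0)):
        raise DomainError("log-averaging requires strictly positive measurements")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log_means = np.nanmean(np.log(arr), axis=1)
    return ReactivityProfile(np.exp(log_means), rna_id=reps.rna_id)


def sample_log_variance(log_measurements: Sequence[float]) -> float:
    """Unbiased sample variance (N-1 divisor) of the log measurements."""
    vals = np.asarray(log_measurements, dtype=float)
    if vals.size < 2:
        raise ValueError("sample variance needs at least 2 measurements")
    return float(np.var(vals, ddof=1))


def kalman_filter_nucleotide(
    log_measurements: Sequence[float],
    prior: GaussianPrior,
    measurement_sd: Optional[float] = None,
) -> KalmanState:
    """Run the scalar Kalman filter on one nucleotide's log measurements.

    Initialization: estimate = prior mean, variance = prior variance.
    Each iteration computes the gain K_i = var_{i-1} / (var_{i-1} + sw2),
    moves the estimate by K_i times the innovation, and scales the
    variance by (1 - K_i). ``sw2`` is the sample variance of the
    measurements unless ``measurement_sd`` overrides it (required to
    filter a single measurement).

    Degenerate cases: a zero-SD prior is absolute certainty — the output
    is the prior mean with zero variance regardless of the data; identical
    measurements (sample variance 0) are noise-free, so the output is the
    common value with zero posterior variance.
    """
    vals = np.asarray(log_measurements, dtype=float)
    if vals.size == 0:
        raise ValueError("no measurements")
    if not np.all(np.isfinite(vals)):
        raise DomainError("log measurements must be finite")
    if measurement_sd is not None:
        if measurement_sd < 0:
            raise ValueError("measurement SD override must be >= 0")
        sw2 = float(measurement_sd) ** 2
    else:
        if vals.size < 2:
            raise ValueError(
                "a single measurement has no sample variance; "
                "pass measurement_sd to filter it anyway"
            )
        sw2 = sample_log_variance(vals)

    if prior.sigma == 0.0:
        return KalmanState(
            estimate=prior.mu,
            variance=0.0,
            gains=(0.0,) * vals.size,
            measurement_variance=sw2,
        )
    if sw2 == 0.0:
        # exact measurements: the sigma_w -> 0 limit of the posterior
        return KalmanState(
            estimate=float(vals[0]),
            variance=0.0,
            gains=(1.0,) + (0.0,) * (vals.size - 1),
            measurement_variance=0.0,
        )

    estimate = prior.mu
    variance = prior.sigma**2
    gains: list[float] = []
    for li in vals:
        total = variance + sw2
        gain = variance / total
        # complement computed directly (not 1 - gain): when the prior is
        # nearly flat gain -> 1 and the subtraction would lose precision
        complement = sw2 / total
        estimate = estimate + gain * (li - estimate)
        variance = complement * variance
        gains.append(gain)
    return KalmanState(
        estimate=float(estimate),
        variance=float(variance),
        gains=tuple(gains),
        measurement_variance=sw2,
    )


PriorSpec = Union[GaussianPrior, Sequence[GaussianPrior]]


def kalman_profile(
    reps: ReplicateSet,
    prior: PriorSpec = DEFAULT_PRIOR,
    measurement_sd: Optional[float] = None,
    return_states: bool = False,
):
    """Kalman-filter every nucleotide and return the data-domain KF profile.

    ``prior`` is either one Gaussian shared by all nucleotides or a
    sequence of per-nucleotide priors (e.g. from :func:`make_ideal_prior`).
    Missing measurements are dropped per nucleotide; nucleotides with
    fewer than 2 usable measurements come out MISSING unless
    ``measurement_sd`` supplies a fixed noise SD.

    With ``return_states=True`` also returns the list of per-nucleotide
    :class:`KalmanState` (None where the nucleotide was skipped).
    """
    arr = reps.measurements
    if np.any(~np.isnan(arr) & (arr <= 0)):
        raise DomainError("Kalman filtering requires strictly positive measurements")
    M = reps.n_nucleotides
    priors = _broadcast_priors(prior, M)
    estimates = np.full(M, np.nan)
    states: list[Optional[KalmanState]] = [None] * M
    n_skipped = 0
    for m in range(M):
        row = arr[m]
        vals = row[~np.isnan(row)]
        if vals.size == 0 or (vals.size < 2 and measurement_sd is None):
            n_skipped += 1
            continue
        state = kalman_filter_nucleotide(np.log(vals), priors[m], measurement_sd)
        states[m] = state
        estimates[m] = np.exp(state.estimate)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} nucleotide(s) had fewer than 2 usable measurements "
            "and were set to missing",
            stacklevel=2,
        )
    profile = ReactivityProfile(estimates, rna_id=reps.rna_id)
    return (profile, states) if return_states else profile


def fit_prior(log_reactivities: Sequence[float]) -> GaussianPrior:
    """Moment-match a Gaussian to log reactivities (mean, N-1 sample SD)."""
    vals = np.asarray(log_reactivities, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite values to fit a prior")
    return GaussianPrior(mu=float(np.mean(vals)), sigma=float(np.std(vals, ddof=1)))


def make_ideal_prior(
    truth_log: ReactivityProfile, spec: IdealPriorSpec
) -> list[GaussianPrior]:
    """Per-nucleotide priors centred at l_m + mu_offset with SD spec.sigma."""
    if truth_log.domain != "log":
        raise DomainError("ideal priors are built from a log-domain truth profile")
    arr = truth_log.reactivities
    if np.any(np.isnan(arr)):
        raise ValueError("truth profile must have no missing values")
    return [GaussianPrior(mu=float(l) + spec.mu_offset, sigma=spec.sigma) for l in arr]


def posterior_closed_form(
    log_measurements: Sequence[float], prior: GaussianPrior, sw2: Optional[float] = None
) -> tuple[float, float]:
    """Closed-form conjugate-normal posterior (mean, variance).

    For N measurements of mean l_bar with noise variance sw2 and prior
    N(mu0, sigma0^2):

        mean = (mu0/sigma0^2 + N*l_bar/sw2) / (1/sigma0^2 + N/sw2)
        var  = 1 / (1/sigma0^2 + N/sw2)

    The iterative filter must reproduce this exactly; it is exposed for
    cross-checking and for reasoning about shrinkage.
    """
    vals = np.asarray(log_measurements, dtype=float)
    if sw2 is None:
        sw2 = sample_log_variance(vals)
    if prior.sigma == 0.0:
        return prior.mu, 0.0
    if sw2 == 0.0:
        return float(vals[0]), 0.0
    prior_prec = 1.0 / prior.sigma**2
    data_prec = vals.size / sw2
    var = 1.0 / (prior_prec + data_prec)
    mean = var * (prior.mu * prior_prec + float(np.mean(vals)) * data_prec)
    return mean, var


def _broadcast_priors(prior: PriorSpec, M: int) -> Sequence[GaussianPrior]:
    if isinstance(prior, GaussianPrior):
        return [prior] * M
    priors = list(prior)
    if len(priors) != M:
        raise ValueError(f"got {len(priors)} priors for {M} nucleotides")
    return priors
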