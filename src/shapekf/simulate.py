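"""Simulate ground-truth profiles and replicates under the log-normal noise model.

A nucleotide's log reactivity l_m is fixed; each replicate observes
l_mi = l_m + w_mi with w_mi ~ N(0, sigma_wm) independent across replicates,
i.e. data-domain measurements r_mi = s_m * exp(w_mi) carry multiplicative
noise. The per-nucleotide noise SD sigma_wm is drawn once per nucleotide
from a uniform noise regime and shared by all N replicates of that
nucleotide.

Regimes are calibrated against log-domain SDs observed in real replicate
sets: low covers sigma in (0, 0.5), medium (0.5, 1), high (1, 1.5).
Simulated replicates are emitted un-renormalized — the noise model
describes post-normalization variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from shapekf.io_formats import DomainError, ReactivityProfile


@dataclass(frozen=True)
class NoiseRegime:
    """Uniform bounds on the per-nucleotide log-domain noise SD."""

    sigma_min: float
    sigma_max: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (0 <= self.sigma_min <= self.sigma_max):
            raise ValueError("need 0 <= sigma_min <= sigma_max")


#: Presets calibrated on real replicate variability.
NOISE_REGIMES = {
    "low": NoiseRegime(0.0, 0.5, "low"),
    "medium": NoiseRegime(0.5, 1.0, "medium"),
    "high": NoiseRegime(1.0, 1.5, "high"),
}


def get_regime(regime: "NoiseRegime | str") -> NoiseRegime:
    """Resolve a regime preset name or pass through a NoiseRegime."""
    if isinstance(regime, NoiseRegime):
        return regime
    try:
        return NOISE_REGIMES[regime]
    except KeyError:
        raise ValueError(
            f"unknown noise regime {regime!r}; choose from {sorted(NOISE_REGIMES)}"
        ) from None


@dataclass(frozen=True)
class ReplicateSet:
    """M x N matrix of data-domain measurements for one RNA.

    Column i is replicate i. For simulated sets the generating ground
    truth and per-nucleotide noise SDs are retained so that estimation
    error can be measured afterwards.
    """

    measurements: np.ndarray
    rna_id: str = ""
    ground_truth: Optional[ReactivityProfile] = None
    noise_sds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.measurements, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("measurements must be a non-empty M x N matrix")
        object.__setattr__(self, "measurements", arr)
        if self.noise_sds is not None:
            sds = np.asarray(self.noise_sds, dtype=float)
            if sds.shape != (arr.shape[0],) or np.any(sds < 0):
                raise ValueError("noise_sds must be length M and non-negative")
            object.__setattr__(self, "noise_sds", sds)
        if self.ground_truth is not None and len(self.ground_truth) != arr.shape[0]:
            raise ValueError("ground truth length must match measurement rows")

    @property
    def n_nucleotides(self) -> int:
        return int(self.measurements.shape[0])

    @property
    def n_replicates(self) -> int:
        return int(self.measurements.shape[1])

    def replicate(self, i: int) -> ReactivityProfile:
        """Replicate i (0-based column) as a data-domain profile."""
        return ReactivityProfile(self.measurements[:, i].copy(), rna_id=f"{self.rna_id}_rep{i + 1}")


def generate_ground_truth(
    M: int, prior: "GaussianPrior | tuple[float, float]", rng: np.random.Generator
) -> ReactivityProfile:
    """Draw a synthetic ground-truth profile from a log-normal reactivity model.

    Log reactivities l_m are sampled i.i.d. from N(mu, sigma) and
    exponentiated, emulating the strongly right-skewed distribution of
    normalized SHAPE reactivities. The shipped default prior
    (mu = -1.74, sigma = 1.52) reproduces a database-scale reactivity
    distribution.
    """
    mu, sigma = _prior_params(prior)
    if M < 1:
        raise ValueError("M must be >= 1")
    if sigma < 0:
        raise ValueError("prior sigma must be >= 0")
    log_truth = rng.normal(mu, sigma, size=M)
    return ReactivityProfile(np.exp(log_truth), rna_id="synthetic")


def sample_noise_sd(
    regime: "NoiseRegime | str", M: int, rng: np.random.Generator
) -> np.ndarray:
    """One sigma_wm per nucleotide, drawn from Uniform(sigma_min, sigma_max)."""
    regime = get_regime(regime)
    return rng.uniform(regime.sigma_min, regime.sigma_max, size=M)


def simulate_replicates(
    truth: ReactivityProfile,
    N: int,
    regime: "NoiseRegime | str",
    rng: np.random.Generator,
    noise_sds: Optional[np.ndarray] = None,
) -> ReplicateSet:
    """Simulate N replicates of ``truth`` under the log-normal noise model.

    For each nucleotide m a single sigma_wm is drawn from the regime
    (or taken from ``noise_sds``) and shared across the N replicates;
    log measurements are l_m + N(0, sigma_wm) draws, exponentiated back
    to the data domain. Draws are consumed in position order so a prefix
    of nucleotides is stable under extension of M.
    """
    if truth.domain != "data":
        raise DomainError("ground truth must be a data-domain profile")
    if N < 1:
        raise ValueError("need at least one replicate")
    arr = truth.reactivities
    if np.any(~np.isnan(arr) & (arr <= 0)):
        raise DomainError("ground truth must be strictly positive; preprocess first")
    M = len(truth)
    if noise_sds is None:
        noise_sds = sample_noise_sd(regime, M, rng)
    else:
        noise_sds = np.asarray(noise_sds, dtype=float)
        if noise_sds.shape != (M,):
            raise ValueError("noise_sds must have one entry per nucleotide")
    with np.errstate(invalid="ignore"):
        log_truth = np.log(arr)
    noise = rng.normal(0.0, 1.0, size=(M, N)) * noise_sds[:, None]
    measurements = np.exp(log_truth[:, None] + noise)
    return ReplicateSet(
        measurements=measurements,
        rna_id=truth.rna_id,
        ground_truth=truth,
        noise_sds=noise_sds,
    )


def simulate_replicates_normal(
    truth: ReactivityProfile,
    N: int,
    sigma_z: float,
    rng: np.random.Generator,
) -> ReplicateSet:
    """Replicates under the additive data-domain Gaussian model (didactic only).

    r_mi = s_m + z_mi with z_mi ~ N(0, sigma_z). Measurements may come out
    non-positive; this family exists for contrast with the log-normal
    model and is never the default.
    """
    if truth.domain != "data":
        raise DomainError("ground truth must be a data-domain profile")
    if N < 1 or sigma_z < 0:
        raise ValueError("need N >= 1 and sigma_z >= 0")
    arr = truth.reactivities
    measurements = arr[:, None] + rng.normal(0.0, sigma_z, size=(len(truth), N))
    return ReplicateSet(measurements=measurements, rna_id=truth.rna_id, ground_truth=truth)


def _prior_params(prior) -> tuple[float, float]:
    if hasattr(prior, "mu") and hasattr(prior, "sigma"):
        return float(prior.mu), float(prior.sigma)
    mu, sigma = prior
    return float(mu), float(sigma)
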