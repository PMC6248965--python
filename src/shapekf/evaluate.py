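"""Accuracy and noise-structure diagnostics.

Estimation error is measured as log-domain RMS between an estimated and a
ground-truth profile. Structure-prediction agreement is scored with the
Matthews correlation coefficient over base-pair confusion counts, using
the universe of all M(M-1)/2 unordered position pairs. The
heteroskedasticity diagnostic regresses log(SD) on log(mean) of replicate
measurements per nucleotide: a slope near 1 means the SD is proportional
to the mean, the signature of multiplicative (log-normal) noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from shapekf.io_formats import DomainError, ReactivityProfile, SecondaryStructure
from shapekf.simulate import ReplicateSet


@dataclass(frozen=True)
class ConfusionCounts:
    """Base-pair confusion counts between a predicted and reference structure."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MeanSdFit:
    """OLS fit of log(SD) against log(mean) of replicate measurements."""

    slope: float
    intercept: float
    n_points: int


def rms_error(
    estimates: ReactivityProfile, truth: ReactivityProfile
) -> float:
    """Root-mean-square error between two log-domain profiles.

    Positions missing in either profile are excluded; the divisor is the
    number of positions actually compared.
    """
    if estimates.domain != "log" or truth.domain != "log":
        raise DomainError("rms_error compares log-domain profiles; transform first")
    if len(estimates) != len(truth):
        raise ValueError("profiles must have equal length")
    a, b = estimates.reactivities, truth.reactivities
    mask = ~np.isnan(a) & ~np.isnan(b)
    if not np.any(mask):
        raise ValueError("no positions are non-missing in both profiles")
    diff = a[mask] - b[mask]
    return float(np.sqrt(np.mean(diff**2)))


def rms_error_data_domain(
    estimates: ReactivityProfile, truth: ReactivityProfile
) -> float:
    """RMS error on raw reactivities (non-default; the log domain is standard)."""
    if estimates.domain != "data" or truth.domain != "data":
        raise DomainError("expects data-domain profiles")
    if len(estimates) != len(truth):
        raise ValueError("profiles must have equal length")
    a, b = estimates.reactivities, truth.reactivities
    mask = ~np.isnan(a) & ~np.isnan(b)
    if not np.any(mask):
        raise ValueError("no positions are non-missing in both profiles")
    return float(np.sqrt(np.mean((a[mask] - b[mask]) ** 2)))


def confusion_counts(
    predicted: SecondaryStructure, reference: SecondaryStructure
) -> ConfusionCounts:
    """Count base pairs over the universe of all M(M-1)/2 unordered pairs."""
    if predicted.length != reference.length:
        raise ValueError("structures must have equal length")
    M = predicted.length
    tp = len(predicted.pairs & reference.pairs)
    fp = len(predicted.pairs - reference.pairs)
    fn = len(reference.pairs - predicted.pairs)
    universe = M * (M - 1) // 2
    tn = universe - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal sum is zero."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    denom_factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in denom_factors):
        return 0.0
    num = tp * tn - fp * fn
    denom = float(np.sqrt(np.prod(np.array(denom_factors, dtype=float))))
    return float(num / denom)


def structure_mcc(
    predicted: SecondaryStructure, reference: SecondaryStructure
) -> float:
    """MCC between two structures (confusion counting + Eq.-style MCC)."""
    return mcc(confusion_counts(predicted, reference))


def mean_sd_loglog_fit(reps: ReplicateSet) -> MeanSdFit:
    """Regress log(SD) on log(mean) of data-domain measurements per nucleotide.

    Non-positive measurements are excluded (incompatible with the log-log
    plot); nucleotides need >= 2 positive measurements, and those with
    zero SD are dropped. Under multiplicative noise the slope is ~1.
    """
    arr = reps.measurements.copy()
    arr[~np.isnan(arr) & (arr <= 0)] = np.nan
    means: list[float] = []
    sds: list[float] = []
    for row in arr:
        vals = row[~np.isnan(row)]
        if vals.size < 2:
            continue
        sd = float(np.std(vals, ddof=1))
        if sd <= 0:
            continue
        means.append(float(np.mean(vals)))
        sds.append(sd)
    if len(means) < 2:
        raise ValueError("need at least 2 nucleotides with positive mean and SD")
    res = stats.linregress(np.log(means), np.log(sds))
    return MeanSdFit(slope=float(res.slope), intercept=float(res.intercept), n_points=len(means))


def rms_heatmap(
    reps: ReplicateSet,
    estimates: ReactivityProfile,
    truth_edges: Sequence[float],
    sigma_edges: Sequence[float],
) -> np.ndarray:
    """Bin nucleotides by (ground truth s_m, noise SD sigma_wm) and compute per-bin RMS.

    ``reps`` must carry ground truth and noise SDs (a simulated set);
    ``estimates`` is a data-domain combined profile. Returns a
    (len(truth_edges)-1, len(sigma_edges)-1) grid of log-domain RMS
    values, NaN for empty bins. Rows index ground-truth bins, columns
    noise bins.
    """
    if reps.ground_truth is None or reps.noise_sds is None:
        raise ValueError("rms_heatmap needs a simulated set with truth and noise SDs")
    if estimates.domain != "data":
        raise DomainError("estimates must be a data-domain profile")
    if len(estimates) != reps.n_nucleotides:
        raise ValueError("estimate length must match the replicate set")
    s = reps.ground_truth.reactivities
    est = estimates.reactivities
    ok = ~np.isnan(s) & ~np.isnan(est)
    log_err2 = np.full(s.shape, np.nan)
    log_err2[ok] = (np.log(est[ok]) - np.log(s[ok])) ** 2

    t_edges = np.asarray(truth_edges, dtype=float)
    g_edges = np.asarray(sigma_edges, dtype=float)
    grid = np.full((t_edges.size - 1, g_edges.size - 1), np.nan)
    t_bin = np.digitize(s, t_edges) - 1
    g_bin = np.digitize(reps.noise_sds, g_edges) - 1
    for ti in range(t_edges.size - 1):
        for gi in range(g_edges.size - 1):
            sel = ok & (t_bin == ti) & (g_bin == gi)
            if np.any(sel):
                grid[ti, gi] = np.sqrt(np.mean(log_err2[sel]))
    return grid
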