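"""Box-plot outlier detection and top-band (2%-scale) normalization.

The model-free normalization used across the SHAPE literature: flag the
most reactive nucleotides as outliers with the box-plot rule (values more
than 1.5 IQR above the upper quartile, capped at 5% of the data for RNAs
shorter than 100 nt and 10% otherwise), average a top band of the
remaining highly reactive nucleotides (default top 10%) to obtain the
normalization factor, then divide the entire profile — outliers and
negative values included — by that factor. On the normalized scale most
reactivities fall between 0 and 2.

Two variants are provided, differing in whether the outliers are excluded
from (the default, ``"exclude"``) or retained in (``"include"``) the
factor computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from shapekf.io_formats import DomainError, ReactivityProfile

DEFAULT_TOP_FRACTION = 0.10

#: Outlier caps from the box-plot convention: at most 5% of the data for
#: RNAs shorter than 100 nt, at most 10% for longer RNAs.
SHORT_RNA_CAP = 0.05
LONG_RNA_CAP = 0.10
SHORT_RNA_LENGTH = 100


@dataclass(frozen=True)
class NormalizationResult:
    factor: float
    outlier_positions: frozenset[int]
    normalized: ReactivityProfile
    variant: str


def detect_outliers_boxplot(
    profile: ReactivityProfile, quantile_method: str = "linear"
) -> frozenset[int]:
    """Flag upper-tail outliers by the box-plot rule; returns 1-based positions.

    Candidates are non-missing values above Q3 + 1.5*IQR, with quartiles
    computed by linear interpolation between order statistics (numpy's
    default, the "type 7" convention). The candidate set is capped at 5%
    (RNAs < 100 nt) or 10% (>= 100 nt) of the non-missing count; when the
    cap binds the largest values are kept, ties broken toward the lower
    position index.
    """
    if profile.domain != "data":
        raise DomainError("outlier detection operates on data-domain profiles")
    arr = profile.reactivities
    usable = np.flatnonzero(~np.isnan(arr))
    if usable.size < 4:
        raise ValueError("need at least 4 non-missing values for a box-plot analysis")
    vals = arr[usable]
    q1, q3 = np.percentile(vals, [25, 75], method=quantile_method)
    threshold = q3 + 1.5 * (q3 - q1)
    candidates = usable[arr[usable] > threshold]
    cap_frac = SHORT_RNA_CAP if len(profile) < SHORT_RNA_LENGTH else LONG_RNA_CAP
    cap = int(math.floor(cap_frac * usable.size))
    if candidates.size > cap:
        # keep the cap largest; stable sort on -value preserves position order for ties
        order = np.argsort(-arr[candidates], kind="stable")
        candidates = candidates[order[:cap]]
    return frozenset(int(i) + 1 for i in candidates)


def normalization_factor(
    profile: ReactivityProfile,
    outliers: frozenset[int] | set[int],
    top_fraction: float = DEFAULT_TOP_FRACTION,
    variant: str = "exclude",
) -> float:
    """Mean of the top reactivity band; the profile is divided by this.

    ``variant="exclude"`` averages the top ``ceil(top_fraction * n_kept)``
    values among non-outlier nucleotides; ``"include"`` performs the same
    computation over all non-missing values, outliers retained.
    """
    if not (0 < top_fraction <= 0.2):
        raise ValueError("top_fraction must lie in (0, 0.2]")
    if variant not in ("exclude", "include"):
        raise ValueError(f"unknown variant {variant!r}")
    arr = profile.reactivities
    usable = np.flatnonzero(~np.isnan(arr))
    if usable.size < 10:
        raise ValueError("need at least 10 non-missing values to normalize")
    if variant == "exclude":
        keep = np.array([i for i in usable if int(i) + 1 not in outliers], dtype=int)
    else:
        keep = usable
    if keep.size == 0:
        raise ValueError("no values left to compute a normalization factor")
    vals = np.sort(arr[keep])[::-1]
    k = int(math.ceil(top_fraction * vals.size))
    factor = float(np.mean(vals[:k]))
    if factor <= 0:
        raise ValueError(f"normalization factor must be positive (got {factor})")
    return factor


def normalize_profile(
    profile: ReactivityProfile,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    variant: str = "exclude",
) -> NormalizationResult:
    """Detect outliers, compute the factor, divide the whole profile by it.

    Every non-missing value — outliers and negatives included — is divided;
    nothing is clipped.
    """
    outliers = detect_outliers_boxplot(profile)
    factor = normalization_factor(profile, outliers, top_fraction, variant)
    normalized = profile.with_values(profile.reactivities / factor)
    return NormalizationResult(
        factor=factor,
        outlier_positions=frozenset(outliers),
        normalized=normalized,
        variant=variant,
    )
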