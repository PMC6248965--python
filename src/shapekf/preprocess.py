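"""Make SHAPE profiles strictly positive and move them between domains.

Normalized SHAPE profiles routinely contain zeros and negative values
(background over-subtraction), which block the log transformation the
noise model needs. Instead of zeroing or absolute-valuing them, each
non-positive reactivity is replaced by the absolute value of a draw from
an empirical "background distribution": the pool of negative reactivities
observed across a reference set of profiles, truncated at a cutoff
(default -0.25) to remove the long tail. Replacement values therefore
land in (0, |cutoff|], the plausible magnitude range of an unreactive
nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from shapekf.io_formats import DomainError, ReactivityProfile

#: Default truncation cutoff for the background distribution.
DEFAULT_BG_CUTOFF = -0.25


@dataclass(frozen=True)
class BackgroundDistribution:
    """Empirical distribution of retained negative reactivities.

    Every sample v satisfies cutoff <= v < 0. The distribution may be
    empty (no negative values were observed); using an empty distribution
    for replacement is an error.
    """

    samples: np.ndarray
    cutoff: float = DEFAULT_BG_CUTOFF

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.size and (np.any(arr >= 0) or np.any(arr < self.cutoff)):
            raise ValueError("background samples must lie in [cutoff, 0)")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0


def build_background_distribution(
    profiles: Iterable[ReactivityProfile] | ReactivityProfile,
    cutoff: float = DEFAULT_BG_CUTOFF,
) -> BackgroundDistribution:
    """Pool negative reactivities across profiles, truncated at ``cutoff``.

    Strictly negative, non-missing values v with v >= cutoff are retained;
    values below the cutoff are discarded to truncate the tail. Zeros are
    replacement targets, never background samples.
    """
    if cutoff >= 0:
        raise ValueError("cutoff must be negative")
    if isinstance(profiles, ReactivityProfile):
        profiles = [profiles]
    pooled: list[np.ndarray] = []
    for p in profiles:
        if p.domain != "data":
            raise DomainError("background distribution is built from data-domain profiles")
        v = p.values
        pooled.append(v[(v < 0) & (v >= cutoff)])
    samples = np.concatenate(pooled) if pooled else np.empty(0)
    return BackgroundDistribution(samples=samples, cutoff=cutoff)


def replace_nonpositive(
    profile: ReactivityProfile,
    bg: BackgroundDistribution,
    rng: np.random.Generator,
) -> ReactivityProfile:
    """Replace every reactivity <= 0 with |v|, v drawn uniformly from ``bg``.

    Positive and missing entries pass through unchanged; the result is
    strictly positive wherever it is not missing. Draws are consumed in
    position order, so results are reproducible for a fixed seed.
    """
    if profile.domain != "data":
        raise DomainError("replace_nonpositive expects a data-domain profile")
    arr = profile.reactivities.copy()
    targets = np.flatnonzero(~np.isnan(arr) & (arr <= 0))
    if targets.size:
        if bg.is_empty:
            raise ValueError(
                "cannot replace non-positive reactivities: background distribution is empty"
            )
        draws = rng.choice(bg.samples, size=targets.size, replace=True)
        arr[targets] = np.abs(draws)
    return profile.with_values(arr)


def to_log_domain(profile: ReactivityProfile) -> ReactivityProfile:
    """Natural log of a strictly positive data-domain profile; NaN propagates."""
    if profile.domain != "data":
        raise DomainError("profile already in log domain")
    arr = profile.reactivities
    bad = np.flatnonzero(~np.isnan(arr) & (arr <= 0))
    if bad.size:
        pos = ", ".join(str(i + 1) for i in bad[:10])
        raise DomainError(
            f"non-positive reactivity at position(s) {pos}; run replace_nonpositive first"
        )
    with np.errstate(invalid="ignore"):
        return profile.with_values(np.log(arr), domain="log")


def from_log_domain(profile: ReactivityProfile) -> ReactivityProfile:
    """Exponentiate a log-domain profile back to the data domain."""
    if profile.domain != "log":
        raise DomainError("profile is not in the log domain")
    return profile.with_values(np.exp(profile.reactivities), domain="data")
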