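"""Simulation-study workflows comparing the replicate combiners.

Each function builds a synthetic database (log reactivities drawn from
the shipped Gaussian prior), simulates replicates under a noise regime,
runs the combiners, and scores them with log-domain RMS. Results come
back as tidy DataFrames ready for TSV export:

* :func:`rms_vs_replicates` — RMS against replicate count N, per regime,
  for log-averaging and Kalman filtering.
* :func:`rms_heatmap_table` — RMS binned by (ground-truth reactivity,
  noise SD) for one combiner.
* :func:`prior_sensitivity_grid` — KF RMS over a grid of ideal-prior
  perturbations (mean offset x prior SD).
* :func:`run_experiment_grid` — drives all three from a single config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from shapekf.denoise import (
    DEFAULT_PRIOR,
    GaussianPrior,
    IdealPriorSpec,
    kalman_profile,
    log_average_profile,
    make_ideal_prior,
)
from shapekf.evaluate import rms_error, rms_heatmap
from shapekf.io_formats import ReactivityProfile
from shapekf.preprocess import to_log_domain
from shapekf.simulate import (
    NOISE_REGIMES,
    NoiseRegime,
    ReplicateSet,
    generate_ground_truth,
    get_regime,
    simulate_replicates,
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full experiment grid at configurable scale."""

    seed: int = 0
    n_nucleotides: int = 10_000
    regimes: tuple[str, ...] = ("low", "medium", "high")
    replicate_counts: tuple[int, ...] = tuple(range(2, 11))
    heatmap_replicate_counts: tuple[int, ...] = (3, 10)
    prior: GaussianPrior = DEFAULT_PRIOR
    prior_offsets: tuple[float, ...] = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0)
    prior_sigmas: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)
    prior_grid_n_replicates: int = 3


def combined_log_rms(
    reps: ReplicateSet, method: str, prior=DEFAULT_PRIOR
) -> float:
    """Log-domain RMS of one combiner against the set's ground truth."""
    if reps.ground_truth is None:
        raise ValueError("replicate set has no ground truth")
    if method == "logavg":
        est = log_average_profile(reps)
    elif method == "kalman":
        est = kalman_profile(reps, prior=prior)
    else:
        raise ValueError(f"unknown method {method!r}")
    return rms_error(to_log_domain(est), to_log_domain(reps.ground_truth))


def rms_vs_replicates(
    config: RunConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """RMS against replicate count for log-averaging and Kalman filtering.

    One synthetic database per (regime, N) cell; columns: regime, N,
    method, rms, n_nucleotides.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows = []
    for regime_name in config.regimes:
        for N in config.replicate_counts:
            truth = generate_ground_truth(config.n_nucleotides, config.prior, rng)
            reps = simulate_replicates(truth, N, regime_name, rng)
            for method in ("logavg", "kalman"):
                rows.append(
                    {
                        "regime": regime_name,
                        "N": N,
                        "method": method,
                        "rms": combined_log_rms(reps, method, config.prior),
                        "n_nucleotides": config.n_nucleotides,
                    }
                )
    return pd.DataFrame(rows)


def rms_heatmap_table(
    config: RunConfig,
    N: int,
    regime: "NoiseRegime | str" = NoiseRegime(0.0, 1.5, "full"),
    n_truth_bins: int = 8,
    n_sigma_bins: int = 8,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-bin RMS over (ground truth, noise SD) for both log-domain combiners.

    The noise SD spans the whole regime range so columns of the grid
    trace the error growth with noise. Columns: method, truth_lo,
    truth_hi, sigma_lo, sigma_hi, rms (NaN rows for empty bins dropped).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    regime = get_regime(regime)
    truth = generate_ground_truth(config.n_nucleotides, config.prior, rng)
    reps = simulate_replicates(truth, N, regime, rng)
    t_edges = np.quantile(truth.reactivities, np.linspace(0, 1, n_truth_bins + 1))
    g_edges = np.linspace(regime.sigma_min, regime.sigma_max + 1e-12, n_sigma_bins + 1)
    rows = []
    for method in ("logavg", "kalman"):
        est = (
            log_average_profile(reps)
            if method == "logavg"
            else kalman_profile(reps, prior=config.prior)
        )
        grid = rms_heatmap(reps, est, t_edges, g_edges)
        for ti in range(grid.shape[0]):
            for gi in range(grid.shape[1]):
                if np.isnan(grid[ti, gi]):
                    continue
                rows.append(
                    {
                        "method": method,
                        "N": N,
                        "truth_lo": t_edges[ti],
                        "truth_hi": t_edges[ti + 1],
                        "sigma_lo": g_edges[gi],
                        "sigma_hi": g_edges[gi + 1],
                        "rms": grid[ti, gi],
                    }
                )
    return pd.DataFrame(rows)


def prior_sensitivity_grid(
    config: RunConfig,
    regime: "NoiseRegime | str" = "high",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """KF RMS over ideal-prior perturbations, with the log-average baseline.

    A single replicate set is reused across the grid so differences are
    attributable to the prior alone. Columns: mu_offset, prior_sigma,
    rms_kalman, rms_logavg.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = generate_ground_truth(config.n_nucleotides, config.prior, rng)
    reps = simulate_replicates(truth, config.prior_grid_n_replicates, regime, rng)
    truth_log = to_log_domain(truth)
    baseline = combined_log_rms(reps, "logavg")
    rows = []
    for offset in config.prior_offsets:
        for sigma in config.prior_sigmas:
            priors = make_ideal_prior(truth_log, IdealPriorSpec(offset, sigma))
            est = kalman_profile(reps, prior=priors)
            rows.append(
                {
                    "mu_offset": offset,
                    "prior_sigma": sigma,
                    "rms_kalman": rms_error(to_log_domain(est), truth_log),
                    "rms_logavg": baseline,
                }
            )
    return pd.DataFrame(rows)


def run_experiment_grid(
    config: RunConfig, outdir: Optional[str | Path] = None
) -> dict[str, pd.DataFrame]:
    """Run the full simulation-study grid; optionally write TSVs to ``outdir``.

    Produces three tables: ``rms_vs_replicates``, ``rms_heatmaps`` (one
    block per N in config.heatmap_replicate_counts), and
    ``prior_sensitivity`` (one block per regime). A fixed seed makes the
    whole grid reproducible.
    """
    rng = np.random.default_rng(config.seed)
    tables: dict[str, pd.DataFrame] = {}
    tables["rms_vs_replicates"] = rms_vs_replicates(config, rng)
    tables["rms_heatmaps"] = pd.concat(
        [rms_heatmap_table(config, N, rng=rng) for N in config.heatmap_replicate_counts],
        ignore_index=True,
    )
    prior_blocks = []
    for regime_name in config.regimes:
        block = prior_sensitivity_grid(config, regime_name, rng)
        block.insert(0, "regime", regime_name)
        prior_blocks.append(block)
    tables["prior_sensitivity"] = pd.concat(prior_blocks, ignore_index=True)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    return tables
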