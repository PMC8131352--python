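"""Observables computed from simulation trajectories.

The quantities of interest are the donation-fraction time series, its mean
over a late (stationary) window — the asymptotic donation fraction — and the
composition of the final population: mean/median CCC, mean beta, and the
CCC histogram with bin width 10 over [0, N].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import PopulationState, RunResult

__all__ = [
    "SummaryStats",
    "donation_fraction_series",
    "asymptotic_donation_fraction",
    "ccc_histogram_bins",
    "final_ccc_stats",
    "summarize_run",
    "stats_frame",
    "histogram_frame",
]


@dataclass(frozen=True)
class SummaryStats:
    """Summary of one replicate: final-population composition plus the
    asymptotic donation fraction (NaN when computed from a state alone)."""

    mean_ccc: float
    median_ccc: float
    mean_beta: float
    asymptotic_donation_fraction: float
    ccc_histogram: np.ndarray


def donation_fraction_series(result: RunResult) -> np.ndarray:
    """Per-generation fraction of donation acts per agent-round."""
    if result.generations == 0:
        raise ValueError("empty run result")
    return result.donation_fractions


def asymptotic_donation_fraction(result: RunResult, tail_fraction: float = 0.1) -> float:
    """Mean donation fraction over the final ``ceil(tail_fraction * G)`` generations.

    The trajectories are stationary long before the end of a default-length
    run, so any late window gives the same answer up to sampling noise; the
    default window is the last 10% of generations.
    """
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must lie in (0, 1]")
    series = donation_fraction_series(result)
    tail = int(np.ceil(tail_fraction * series.shape[0]))
    if tail > series.shape[0]:
        raise ValueError("tail window longer than the series")
    return float(series[-tail:].mean())


def ccc_histogram_bins(n_agents: int, bin_width: float = 10.0) -> np.ndarray:
    """Bin edges [0, 10, 20, ..., >= N]; the last bin is closed at N."""
    return np.arange(0.0, n_agents + bin_width, bin_width)


def final_ccc_stats(
    state: PopulationState, bin_width: float = 10.0, n_max: int | None = None
) -> SummaryStats:
    """Composition statistics of a population state.

    The median of an even-sized population is the midpoint of the two
    central order statistics.  The histogram uses half-open bins
    ``[0, 10), [10, 20), ...`` with the last bin closed at ``n_max``
    (default: the population size N, the upper bound of the CCC scale), so
    the counts always sum to the number of agents.
    """
    edges = ccc_histogram_bins(n_max if n_max is not None else state.n_agents, bin_width)
    hist, _ = np.histogram(state.ccc, bins=edges)
    return SummaryStats(
        mean_ccc=float(state.ccc.mean()),
        median_ccc=float(np.median(state.ccc)),
        mean_beta=float(state.beta.mean()),
        asymptotic_donation_fraction=float("nan"),
        ccc_histogram=hist,
    )


def summarize_run(result: RunResult, tail_fraction: float = 0.1) -> SummaryStats:
    """Full per-replicate summary: final-state composition plus the
    asymptotic donation fraction of the trajectory."""
    stats = final_ccc_stats(result.final_state)
    return SummaryStats(
        mean_ccc=stats.mean_ccc,
        median_ccc=stats.median_ccc,
        mean_beta=stats.mean_beta,
        asymptotic_donation_fraction=asymptotic_donation_fraction(result, tail_fraction),
        ccc_histogram=stats.ccc_histogram,
    )


def stats_frame(stats: SummaryStats) -> dict:
    """Flat scalar fields of a summary (histogram excluded), for tabulation."""
    return {
        "mean_ccc": stats.mean_ccc,
        "median_ccc": stats.median_ccc,
        "mean_beta": stats.mean_beta,
        "asymptotic_donation_fraction": stats.asymptotic_donation_fraction,
    }


def histogram_frame(
    stats: SummaryStats, n_agents: int, bin_width: float = 10.0
) -> pd.DataFrame:
    """Long-format histogram table with columns bin_left, bin_right, count."""
    edges = ccc_histogram_bins(n_agents, bin_width)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": stats.ccc_histogram,
    })
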