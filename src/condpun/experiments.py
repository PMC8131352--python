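"""Replicate execution and the (w x inflicted-cost) condition sweep.

A sweep runs the full Cartesian grid of punishment-opportunity
probabilities and inflicted costs, several replicates per cell, each with a
seed derived deterministically from the root seed and the cell's identity —
so any single cell can be recomputed in isolation and reproduces its row
exactly, independent of grid shape or execution order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import RunResult, run_simulation
from .metrics import SummaryStats, ccc_histogram_bins, stats_frame, summarize_run
from .params import ModelParams

__all__ = ["SweepSpec", "SweepTable", "derive_seed", "run_replicates", "run_sweep"]

_STAT_COLS = ["mean_ccc", "median_ccc", "mean_beta", "asymptotic_donation_fraction"]


def derive_seed(root_seed: int, replicate: int, salt: tuple = ()) -> int:
    """Deterministic per-run seed from the root seed, a replicate index and
    an optional condition salt (integers).  Kept below 2**31."""
    entropy = (int(root_seed), *[int(s) for s in salt], int(replicate))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)


def _condition_salt(w: float, cost: float) -> tuple[int, int]:
    # scale to integers so the salt is exact for any reasonably-rounded grid value
    return (int(round(w * 1_000_000)), int(round(cost * 1_000_000)))


@dataclass(frozen=True)
class SweepSpec:
    """The experimental grid: full Cartesian product of ``w_values`` and
    ``inflicted_costs``, ``replicates`` independent runs per cell."""

    base_params: ModelParams = field(default_factory=ModelParams)
    w_values: tuple = (1.0, 0.5)
    inflicted_costs: tuple = (3.0, 0.9)
    replicates: int = 20
    root_seed: int = 0
    tail_fraction: float = 0.1
    stride: int = 20

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates: must be >= 1")
        if self.stride < 1:
            raise ValueError("stride: must be >= 1")
        for w in self.w_values:
            if not 0.0 <= w <= 1.0:
                raise ValueError("w_values: every w must lie in [0, 1]")
        for c in self.inflicted_costs:
            if c < 0:
                raise ValueError("inflicted_costs: costs must be non-negative")

    @property
    def conditions(self) -> list[tuple[float, float]]:
        return list(itertools.product(self.w_values, self.inflicted_costs))

    def cell_params(self, w: float, cost: float) -> ModelParams:
        return self.base_params.replace(punish_probability=w, inflicted_cost=cost)

    def cell_seed(self, w: float, cost: float, replicate: int) -> int:
        return derive_seed(self.root_seed, replicate, _condition_salt(w, cost))


@dataclass
class SweepTable:
    """Aggregated sweep output.

    ``replicate_rows``: one row per (w, cost, replicate) with the summary
    statistics and the seed used.  ``aggregates``: one row per condition
    with replicate means and the between-replicate s.d. of the final mean
    CCC.  ``histograms``: pooled final-population CCC histograms in long
    format.  ``timeseries``: donation-fraction trajectories thinned by the
    sweep's stride.
    """

    replicate_rows: pd.DataFrame
    aggregates: pd.DataFrame
    histograms: pd.DataFrame
    timeseries: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Replicate and aggregate rows in one table, flagged by ``is_aggregate``."""
        reps = self.replicate_rows.assign(is_aggregate=False)
        aggs = self.aggregates.assign(is_aggregate=True, replicate=-1, seed=-1)
        return pd.concat([reps, aggs], ignore_index=True)[
            ["w", "inflicted_cost", "replicate", "seed", *_STAT_COLS,
             "sd_mean_ccc", "is_aggregate"]
        ]


def run_replicates(
    params: ModelParams,
    replicates: int,
    root_seed: int,
    salt: tuple = (),
) -> list[RunResult]:
    """Independent replicate runs with seeds derived from ``root_seed``.

    The optional ``salt`` identifies the condition so sweep cells never
    share a random stream.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    return [
        run_simulation(params, derive_seed(root_seed, rep, salt))
        for rep in range(replicates)
    ]


def _summarize_cell(
    w: float, cost: float, spec: SweepSpec
) -> tuple[list[dict], np.ndarray, pd.DataFrame]:
    params = spec.cell_params(w, cost)
    rows = []
    pooled = np.zeros(
        ccc_histogram_bins(params.n_agents).shape[0] - 1, dtype=np.int64
    )
    ts_parts = []
    for rep in range(spec.replicates):
        seed = spec.cell_seed(w, cost, rep)
        result = run_simulation(params, seed)
        stats = summarize_run(result, spec.tail_fraction)
        pooled += stats.ccc_histogram
        rows.append({
            "w": w, "inflicted_cost": cost, "replicate": rep, "seed": seed,
            **stats_frame(stats),
        })
        gens = np.arange(0, result.generations, spec.stride)
        ts_parts.append(pd.DataFrame({
            "w": w, "inflicted_cost": cost, "replicate": rep,
            "generation": gens,
            "donation_fraction": result.donation_fractions[gens],
        }))
    return rows, pooled, pd.concat(ts_parts, ignore_index=True)


def _aggregate(replicate_rows: pd.DataFrame) -> pd.DataFrame:
    grouped = replicate_rows.groupby(["w", "inflicted_cost"], as_index=False)
    aggs = grouped[_STAT_COLS].mean()
    aggs["sd_mean_ccc"] = grouped["mean_ccc"].std(ddof=1)["mean_ccc"].values
    return aggs


def run_sweep(spec: SweepSpec, prior: pd.DataFrame | None = None) -> SweepTable:
    """Execute the full grid; cells already present in ``prior`` are reused.

    ``prior`` is a previously written replicate-row table (e.g. read back
    from ``summary.csv``).  A prior cell with missing or NaN statistics is
    recomputed with a warning.  Histograms and time series are only
    produced for freshly computed cells (the summary rows carry everything
    needed for aggregation).
    """
    rep_rows: list[dict] = []
    hist_rows: list[pd.DataFrame] = []
    ts_rows: list[pd.DataFrame] = []
    n_agents = spec.base_params.n_agents
    edges = ccc_histogram_bins(n_agents)

    for w, cost in spec.conditions:
        reused = None
        if prior is not None and len(prior):
            mask = np.isclose(prior["w"], w) & np.isclose(prior["inflicted_cost"], cost)
            cell = prior.loc[mask & (prior.get("is_aggregate", False) == False)]  # noqa: E712
            if len(cell) == spec.replicates:
                if cell[_STAT_COLS].isna().any().any():
                    warnings.warn(
                        f"cell (w={w}, cost={cost}) has missing statistics; recomputing"
                    )
                else:
                    reused = cell[
                        ["w", "inflicted_cost", "replicate", "seed", *_STAT_COLS]
                    ].to_dict("records")
        if reused is not None:
            rep_rows.extend(reused)
            continue
        rows, pooled, ts = _summarize_cell(w, cost, spec)
        rep_rows.extend(rows)
        ts_rows.append(ts)
        hist_rows.append(pd.DataFrame({
            "w": w, "inflicted_cost": cost,
            "bin_left": edges[:-1], "bin_right": edges[1:], "count": pooled,
        }))

    replicate_rows = pd.DataFrame(rep_rows)
    aggregates = _aggregate(replicate_rows)
    histograms = (
        pd.concat(hist_rows, ignore_index=True) if hist_rows else pd.DataFrame(
            columns=["w", "inflicted_cost", "bin_left", "bin_right", "count"]
        )
    )
    timeseries = (
        pd.concat(ts_rows, ignore_index=True) if ts_rows else pd.DataFrame(
            columns=["w", "inflicted_cost", "replicate", "generation",
                     "donation_fraction"]
        )
    )
    return SweepTable(replicate_rows, aggregates, histograms, timeseries)
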