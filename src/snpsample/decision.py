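"""Trajectory summaries and the Evanno-style plateau detector.

Each (parameter, grid value) cell of a trajectory table is summarised
by the mean, the sample standard deviation and a Student-t 95%
confidence interval of the mean across replicates.  The plateau
statistic adapts Evanno's delta-K from STRUCTURE model choice to
parameter trajectories: for an interior grid value k with neighbours
k- and k+,

    delta(k) = |m(k+) - 2 m(k) + m(k-)| / sd(k)

i.e. the absolute second difference of cell means scaled by the cell's
replicate spread.  Its peak marks the grid value beyond which further
increase changes the estimate little; ties break toward the smaller
grid value because minimality is the goal.  Second differences are
taken on grid index, which for equally spaced grids leaves the argmax
unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from snpsample.genotype_io import GenotypeMatrix
from snpsample.resampler import ResamplingDesign, run_replicate_sweep, run_samplesize_sweep

SUMMARY_COLUMNS = (
    "parameter", "unit", "axis", "grid_value", "n_replicates",
    "mean", "sd", "ci_low", "ci_high",
)


def summarize(table: pd.DataFrame, ci_method: str = "t") -> pd.DataFrame:
    """Per-cell mean, sample SD and 95% CI of the mean.

    ``ci_method="t"`` (default) uses mean +/- t(0.975, x-1) * sd/sqrt(x);
    ``"normal"`` replaces the t quantile with 1.96.  Cells with fewer
    than two replicates get NaN SD/CI and are flagged via the NaNs.
    """
    if ci_method not in ("t", "normal"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    rows = []
    group_cols = ["parameter", "unit", "axis", "grid_value"]
    for key, cell in table.groupby(group_cols, sort=True):
        values = cell["value"].to_numpy(dtype=float)
        x = values.size
        mean = float(values.mean())
        if x >= 2:
            sd = float(values.std(ddof=1))
            q = (
                float(sps.t.ppf(0.975, x - 1))
                if ci_method == "t"
                else float(sps.norm.ppf(0.975))
            )
            half = q * sd / math.sqrt(x)
            ci_low, ci_high = mean - half, mean + half
        else:
            sd = ci_low = ci_high = float("nan")
        rows.append((*key, x, mean, sd, ci_low, ci_high))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


@dataclass
class DeltaKResult:
    """Second-difference statistic along one grid, plus its peak."""

    parameter: str
    unit: str
    axis: str
    grid: list[int]
    delta: dict[int, float] = field(default_factory=dict)
    optimum: int | None = None
    flat: bool = False  # all interior deltas zero

    def interior(self) -> list[int]:
        return self.grid[1:-1]


def delta_k(summary: pd.DataFrame, parameter: str, unit: str | None = None) -> DeltaKResult:
    """Compute delta(k) over the grid of one parameter's summary rows.

    ``summary`` is the output of :func:`summarize`, filtered here to
    ``parameter`` (and ``unit`` when several populations/pairs are
    present).  A cell with sd = 0 yields +inf when the second
    difference is nonzero, else 0 — a noiseless kink is infinitely
    sharp, a noiseless line is perfectly flat.
    """
    sel = summary[summary["parameter"] == parameter]
    if unit is not None:
        sel = sel[sel["unit"] == unit]
    units = sel["unit"].unique()
    if len(units) != 1:
        raise ValueError(
            f"parameter {parameter!r} spans units {sorted(units)}; pass unit="
        )
    axes = sel["axis"].unique()
    if len(axes) != 1:
        raise ValueError(f"summary mixes grid axes {sorted(axes)}")
    sel = sel.sort_values("grid_value")
    grid = [int(v) for v in sel["grid_value"]]
    if len(grid) < 3:
        raise ValueError(f"delta-K needs >= 3 grid points, got {len(grid)}")
    means = sel["mean"].to_numpy(dtype=float)
    sds = sel["sd"].to_numpy(dtype=float)
    if np.isnan(means).any() or np.isnan(sds).any():
        raise ValueError("delta-K needs defined means and sds at every grid point")

    result = DeltaKResult(
        parameter=parameter, unit=str(units[0]), axis=str(axes[0]), grid=grid
    )
    for i in range(1, len(grid) - 1):
        numer = abs(means[i + 1] - 2.0 * means[i] + means[i - 1])
        if sds[i] == 0.0:
            result.delta[grid[i]] = math.inf if numer > 0.0 else 0.0
        else:
            result.delta[grid[i]] = numer / sds[i]
    return result


def select_optimum(dk: DeltaKResult) -> int:
    """Grid value at the delta-K peak; ties break toward the smaller value.

    When every interior delta is zero the trajectory is flat and the
    smallest interior grid value is returned with ``dk.flat`` set — any
    grid value estimates equally well, so the cheapest wins.
    """
    if not dk.delta:
        raise ValueError("no interior delta values")
    best = max(dk.delta.values())
    if best == 0.0:
        dk.flat = True
        dk.optimum = dk.interior()[0]
        return dk.optimum
    dk.optimum = min(k for k, v in dk.delta.items() if v == best)
    return dk.optimum


# ---------------------------------------------------------------------
# two-stage orchestration


@dataclass
class DecisionReport:
    """Bundle of both sweeps, their summaries, delta-K curves and optima."""

    replicate_summary: pd.DataFrame
    samplesize_summary: pd.DataFrame
    x_delta: dict[tuple[str, str], DeltaKResult]
    n_delta: dict[tuple[str, str], DeltaKResult]
    x_opt: dict[tuple[str, str], int]
    n_min: dict[tuple[str, str], int]
    x_opt_overall: int
    n_min_overall: int
    ci_overlap: dict[tuple[str, str], bool]
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        def _key(k: tuple[str, str]) -> str:
            return f"{k[0]}@{k[1]}"

        payload = json.dumps(
            {
                "seed": self.seed,
                "x_opt": {_key(k): v for k, v in self.x_opt.items()},
                "n_min": {_key(k): v for k, v in self.n_min.items()},
                "x_opt_overall": self.x_opt_overall,
                "n_min_overall": self.n_min_overall,
                "ci_overlap_with_largest_n": {
                    _key(k): v for k, v in self.ci_overlap.items()
                },
                "x_delta": {
                    _key(k): {str(g): dk.delta[g] for g in dk.interior()}
                    for k, dk in self.x_delta.items()
                },
                "n_delta": {
                    _key(k): {str(g): dk.delta[g] for g in dk.interior()}
                    for k, dk in self.n_delta.items()
                },
            },
            indent=2,
            allow_nan=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _per_series_optima(
    summary: pd.DataFrame,
) -> tuple[dict[tuple[str, str], DeltaKResult], dict[tuple[str, str], int]]:
    deltas: dict[tuple[str, str], DeltaKResult] = {}
    optima: dict[tuple[str, str], int] = {}
    for (param, unit), _ in summary.groupby(["parameter", "unit"], sort=True):
        dk = delta_k(summary, param, unit)
        deltas[(param, unit)] = dk
        optima[(param, unit)] = select_optimum(dk)
    return deltas, optima


def determine(
    G: GenotypeMatrix,
    design: ResamplingDesign | None = None,
    x_opt: int | None = None,
) -> DecisionReport:
    """Run the full two-stage protocol and pick x_opt and n_min.

    Stage 1 sweeps the replicate count at ``design.fixed_n`` and picks
    the delta-K peak per parameter series; stage 2 sweeps the sample
    size at the most conservative of those (the maximum, overridable
    via ``x_opt``) and picks the delta-K peak per series again.  The
    report also cross-checks, per series, whether the n_min cell's 95%
    CI overlaps the largest-n cell's CI (parameter series disagree in
    practice, so per-series optima and the conservative maxima are both
    reported).
    """
    if design is None:
        design = ResamplingDesign()
    stage1 = run_replicate_sweep(G, design)
    x_summary = summarize(stage1)
    x_deltas, x_optima = _per_series_optima(x_summary)
    chosen_x = x_opt if x_opt is not None else max(x_optima.values())

    stage2 = run_samplesize_sweep(G, design, chosen_x)
    n_summary = summarize(stage2)
    n_deltas, n_optima = _per_series_optima(n_summary)

    n_largest = max(design.sample_size_grid)
    ci_overlap: dict[tuple[str, str], bool] = {}
    for key, n_min in n_optima.items():
        param, unit = key
        sel = n_summary[
            (n_summary["parameter"] == param) & (n_summary["unit"] == unit)
        ].set_index("grid_value")
        lo1, hi1 = sel.loc[n_min, "ci_low"], sel.loc[n_min, "ci_high"]
        lo2, hi2 = sel.loc[n_largest, "ci_low"], sel.loc[n_largest, "ci_high"]
        ci_overlap[key] = bool(max(lo1, lo2) <= min(hi1, hi2))

    return DecisionReport(
        replicate_summary=x_summary,
        samplesize_summary=n_summary,
        x_delta=x_deltas,
        n_delta=n_deltas,
        x_opt=x_optima,
        n_min=n_optima,
        x_opt_overall=chosen_x,
        n_min_overall=max(n_optima.values()),
        ci_overlap=ci_overlap,
        seed=design.seed,
    )
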