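import math

import numpy as np
import pandas as pd
import pytest

from snpsample.decision import (
    delta_k,
    determine,
    select_optimum,
    summarize,
)
from snpsample.resampler import ResamplingDesign, TRAJECTORY_COLUMNS
from snpsample.synthetic_data import SimulationConfig, simulate


def trajectory(values_by_grid, parameter="uHe", unit="pop1", axis="n"):
    rows = [
        (parameter, unit, axis, g, r, v)
        for g, values in values_by_grid.items()
        for r, v in enumerate(values)
    ]
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def summary_from(means, sds, grid=None, parameter="uHe", unit="pop1", axis="n"):
    grid = grid or list(range(2, 2 + len(means)))
    rows = [
        (parameter, unit, axis, g, 30, m, s, m - s, m + s)
        for g, m, s in zip(grid, means, sds)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "parameter", "unit", "axis", "grid_value", "n_replicates",
            "mean", "sd", "ci_low", "ci_high",
        ],
    )


class TestSummarize:
    def test_constant_cell(self):
        s = summarize(trajectory({3: [1.0, 1.0, 1.0, 1.0]}))
        row = s.iloc[0]
        assert row["mean"] == 1.0
        assert row["sd"] == 0.0
        assert row["ci_low"] == row["ci_high"] == 1.0

    def test_two_value_cell_uses_t_with_one_df(self):
        s = summarize(trajectory({3: [0.0, 1.0]}))
        row = s.iloc[0]
        sd = math.sqrt(0.5)
        half = 12.7062 * sd / math.sqrt(2)  # t(0.975, 1 df)
        assert row["mean"] == pytest.approx(0.5)
        assert row["sd"] == pytest.approx(sd)
        assert row["ci_low"] == pytest.approx(0.5 - half, rel=1e-4)
        assert row["ci_high"] == pytest.approx(0.5 + half, rel=1e-4)

    def test_singleton_cell_flagged_with_nan(self):
        s = summarize(trajectory({3: [0.7]}))
        assert math.isnan(s.iloc[0]["sd"])
        assert math.isnan(s.iloc[0]["ci_low"])

    def test_ci_contains_mean_and_shrinks_with_replicates(self):
        rng = np.random.default_rng(0)
        t = trajectory({4: list(rng.normal(size=20)), 5: list(rng.normal(size=80))})
        s = summarize(t).set_index("grid_value")
        for g in (4, 5):
            assert s.loc[g, "ci_low"] <= s.loc[g, "mean"] <= s.loc[g, "ci_high"]

    def test_coverage_of_the_mean_is_near_nominal(self):
        """t-based 95% CI covers the true mean ~95% of repeated samplings."""
        rng = np.random.default_rng(42)
        covered = 0
        runs = 400
        for _ in range(runs):
            s = summarize(trajectory({2: list(rng.normal(size=10))}))
            covered += s.iloc[0]["ci_low"] <= 0.0 <= s.iloc[0]["ci_high"]
        assert 0.90 <= covered / runs <= 0.99

    def test_normal_ci_narrower_than_t(self):
        t = trajectory({3: [0.1, 0.4, 0.2, 0.5, 0.3]})
        st = summarize(t).iloc[0]
        sn = summarize(t, ci_method="normal").iloc[0]
        assert sn["ci_high"] - sn["ci_low"] < st["ci_high"] - st["ci_low"]


class TestDeltaK:
    def test_affine_means_give_zero_everywhere(self):
        s = summary_from([1.0, 1.5, 2.0, 2.5, 3.0], [0.2] * 5)
        dk = delta_k(s, "uHe")
        assert list(dk.delta.values()) == pytest.approx([0.0, 0.0, 0.0])

    def test_plateau_at_four_yields_unique_peak(self):
        # ramp to n=4 then flat: curvature only at the plateau onset
        s = summary_from([1.0, 2.0, 3.0, 3.0, 3.0, 3.0], [0.1] * 6)
        dk = delta_k(s, "uHe")
        assert dk.delta == pytest.approx({3: 0.0, 4: 10.0, 5: 0.0, 6: 0.0})
        assert select_optimum(dk) == 4

    def test_zero_sd_with_curvature_is_infinite(self):
        s = summary_from([1.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        dk = delta_k(s, "uHe")
        assert math.isinf(dk.delta[3])

    def test_zero_sd_without_curvature_is_zero(self):
        s = summary_from([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert delta_k(s, "uHe").delta[3] == 0.0

    def test_shift_invariance_and_sd_scaling(self):
        means = [0.2, 0.5, 0.55, 0.8, 0.6]
        sds = [0.1, 0.05, 0.2, 0.1, 0.15]
        base = delta_k(summary_from(means, sds), "uHe").delta
        shifted = delta_k(
            summary_from([m + 3.0 for m in means], sds), "uHe"
        ).delta
        scaled = delta_k(
            summary_from(means, [s * 2 for s in sds]), "uHe"
        ).delta
        for k in base:
            assert shifted[k] == pytest.approx(base[k])
            assert scaled[k] == pytest.approx(base[k] / 2)

    def test_needs_three_grid_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            delta_k(summary_from([1.0, 2.0], [0.1, 0.1]), "uHe")


class TestSelectOptimum:
    def test_tie_breaks_toward_smaller_grid_value(self):
        s = summary_from([0.0, 1.0, 2.0, 2.0, 1.0, 0.0], [0.1] * 6)
        dk = delta_k(s, "uHe")
        peak = max(dk.delta.values())
        ties = [k for k, v in dk.delta.items() if v == peak]
        assert len(ties) >= 2
        assert select_optimum(dk) == min(ties)

    def test_flat_trajectory_returns_smallest_interior_with_flag(self):
        s = summary_from([1.0, 1.0, 1.0, 1.0], [0.3] * 4)
        dk = delta_k(s, "uHe")
        assert select_optimum(dk) == dk.interior()[0]
        assert dk.flat

    def test_single_curvature_point_family_recovered(self):
        # for each interior k*, a ramp-then-plateau trajectory bends at k*
        grid = list(range(2, 9))
        for kstar in grid[1:-1]:
            means = [min(g, kstar) * 1.0 for g in grid]
            dk = delta_k(summary_from(means, [0.1] * len(grid), grid=grid), "uHe")
            assert select_optimum(dk) == kstar


@pytest.fixture(scope="module")
def study():
    cfg = SimulationConfig(
        n_populations=2, n_per_population=10, n_loci=400,
        fst=(0.2, 0.2), missing_rate=0.1, inbreeding=0.2, seed=21,
    )
    G, _ = simulate(cfg)
    return G


@pytest.fixture(scope="module")
def design():
    return ResamplingDesign(
        sample_size_grid=(2, 3, 4, 5, 6),
        replicate_grid=(10, 20, 30, 40),
        snp_subset_size=300,
        fixed_n=3,
        seed=8,
    )


class TestDetermine:
    def test_end_to_end_report(self, study, design):
        report = determine(study, design)
        series = set(report.n_min)
        assert ("FST", "pop1|pop2") in series
        for key, n_min in report.n_min.items():
            assert n_min in design.sample_size_grid[1:-1]
        for key, x_opt in report.x_opt.items():
            assert x_opt in design.replicate_grid[1:-1]
        assert report.n_min_overall == max(report.n_min.values())
        assert set(report.ci_overlap) == series

    def test_rerun_is_identical(self, study, design):
        a = determine(study, design)
        b = determine(study, design)
        assert a.to_json() == b.to_json()

    def test_single_population_omits_fst(self, study, design):
        solo = study.restrict_population("pop1")
        report = determine(solo, design)
        assert all(param != "FST" for param, _ in report.n_min)

    def test_report_serialises(self, study, design, tmp_path):
        report = determine(study, design)
        path = tmp_path / "decision.json"
        report.to_json(path)
        assert path.exists() and path.read_text().startswith("{")
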