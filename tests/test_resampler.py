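import itertools

import numpy as np
import pandas as pd
import pytest

from snpsample.popgen_stats import population_summary
from snpsample.resampler import (
    ResamplingDesign,
    draw_replicate,
    run_replicate_sweep,
    run_samplesize_sweep,
    subset_snps,
)
from snpsample.synthetic_data import SimulationConfig, simulate
from tests.conftest import make_matrix


@pytest.fixture(scope="module")
def small_study():
    """Two 10-individual populations, 200 loci, mild divergence."""
    cfg = SimulationConfig(
        n_populations=2, n_per_population=10, n_loci=200,
        fst=(0.1, 0.1), missing_rate=0.05, seed=123,
    )
    G, _ = simulate(cfg)
    return G


@pytest.fixture(scope="module")
def small_design():
    return ResamplingDesign(
        sample_size_grid=(2, 3, 4, 5),
        replicate_grid=(10, 20, 30),
        snp_subset_size=100,
        fixed_n=3,
        seed=9,
    )


class TestSubsetSnps:
    def test_full_size_is_identity_set(self):
        loci = [f"L{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        assert sorted(subset_snps(loci, 20, rng)) == sorted(loci)

    def test_requested_size_and_uniqueness(self):
        loci = [f"L{i}" for i in range(7460)]
        chosen = subset_snps(loci, 3000, np.random.default_rng(1))
        assert len(chosen) == 3000
        assert len(set(chosen)) == 3000

    def test_deterministic_under_seed(self):
        loci = [f"L{i}" for i in range(50)]
        a = subset_snps(loci, 10, np.random.default_rng(5))
        b = subset_snps(loci, 10, np.random.default_rng(5))
        assert a == b

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            subset_snps(["L1"], 2, np.random.default_rng(0))


class TestDrawReplicate:
    def test_no_duplicates_and_errors(self):
        samples = [f"s{i}" for i in range(10)]
        chosen = draw_replicate(samples, 3, np.random.default_rng(0))
        assert len(set(chosen)) == 3
        with pytest.raises(ValueError):
            draw_replicate(samples, 11, np.random.default_rng(0))

    def test_full_draw_is_whole_population(self):
        samples = [f"s{i}" for i in range(6)]
        assert sorted(draw_replicate(samples, 6, np.random.default_rng(0))) == samples

    def test_inclusion_frequency_is_uniform(self):
        """Each of 10 individuals appears in ~n/N of 1,000 draws of n=3."""
        samples = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(2)
        counts = {s: 0 for s in samples}
        draws = 1000
        for _ in range(draws):
            for s in draw_replicate(samples, 3, rng):
                counts[s] += 1
        # binomial(1000, 0.3): 4 sigma ~ 58
        for s, c in counts.items():
            assert abs(c - 300) < 60, (s, c)


class TestReplicateSweep:
    def test_nesting_small_cells_are_prefixes(self, small_study, small_design):
        table = run_replicate_sweep(small_study, small_design)
        big = table[(table.grid_value == 30) & (table.parameter == "uHe")
                    & (table.unit == "pop1")].sort_values("replicate")
        small = table[(table.grid_value == 10) & (table.parameter == "uHe")
                      & (table.unit == "pop1")].sort_values("replicate")
        np.testing.assert_array_equal(
            small.value.to_numpy(), big.value.to_numpy()[:10]
        )

    def test_cell_counts_exact_and_keys_unique(self, small_study, small_design):
        table = run_replicate_sweep(small_study, small_design)
        counts = table.groupby(["parameter", "unit", "grid_value"]).size()
        for (_, _, x), c in counts.items():
            assert c == x
        assert not table.duplicated(
            ["parameter", "unit", "grid_value", "replicate"]
        ).any()

    def test_bit_reproducible(self, small_study, small_design):
        a = run_replicate_sweep(small_study, small_design)
        b = run_replicate_sweep(small_study, small_design)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_individuals_give_zero_variance(self, small_design):
        calls = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (10, 25))[:, :100]
        G = make_matrix(np.vstack([calls, calls]),
                        populations=["A"] * 10 + ["B"] * 10)
        table = run_replicate_sweep(G, small_design)
        spread = table.groupby(["parameter", "unit", "grid_value"]).value.std(ddof=1)
        assert (spread < 1e-12).all()


class TestSamplesizeSweep:
    def test_full_population_cell_equals_full_data_value(self, small_study):
        design = ResamplingDesign(
            sample_size_grid=(2, 3, 10), replicate_grid=(10, 20),
            snp_subset_size=200, fixed_n=3, seed=4,
        )
        table = run_samplesize_sweep(small_study, design, x_opt=5)
        full = population_summary(small_study, "pop1").mean_ho
        cell = table[(table.parameter == "Ho") & (table.unit == "pop1")
                     & (table.grid_value == 10)].value
        assert cell.to_numpy() == pytest.approx([full] * 5)

    def test_monte_carlo_mean_matches_exhaustive_enumeration(self, six_by_three):
        """Replicate-mean Ho at n=3 agrees with the C(6,3) exhaustive mean."""
        exact = np.mean([
            population_summary(six_by_three.restrict_samples(list(c))).mean_ho
            for c in itertools.combinations(six_by_three.samples, 3)
        ])
        design = ResamplingDesign(
            sample_size_grid=(2, 3), replicate_grid=(10, 2000),
            snp_subset_size=3, fixed_n=3, seed=77,
        )
        table = run_replicate_sweep(six_by_three, design)
        vals = table[(table.parameter == "Ho") & (table.grid_value == 2000)].value
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - exact) < 3 * se + 1e-9

    def test_uhe_correction_absorbs_subsampling_bias(self, small_study):
        """|mean uHe(n=3) - uHe(N)| stays below |mean He(n=3) - He(N)|."""
        G = small_study.restrict_population("pop1")
        full = population_summary(G)
        uhe_vals, he_vals = [], []
        rng = np.random.default_rng(3)
        for _ in range(400):
            ids = draw_replicate(G.samples, 3, rng)
            s = population_summary(G.restrict_samples(ids))
            uhe_vals.append(s.mean_uhe)
            he_vals.append(s.mean_he)
        uhe_gap = abs(np.mean(uhe_vals) - full.mean_uhe)
        he_gap = abs(np.mean(he_vals) - full.mean_he)
        assert uhe_gap < he_gap

    def test_population_smaller_than_n_rejected(self, small_study):
        design = ResamplingDesign(
            sample_size_grid=(2, 3, 11), replicate_grid=(10, 20),
            snp_subset_size=50, fixed_n=3, seed=0,
        )
        with pytest.raises(ValueError, match="cannot draw"):
            run_samplesize_sweep(small_study, design, x_opt=5)


class TestDesignValidation:
    def test_grids_must_increase(self):
        with pytest.raises(ValueError):
            ResamplingDesign(sample_size_grid=(3, 2))
        with pytest.raises(ValueError):
            ResamplingDesign(replicate_grid=(10, 10))

    def test_fixed_n_must_be_on_grid(self):
        with pytest.raises(ValueError):
            ResamplingDesign(fixed_n=9)
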