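"""Individual-resampling engine over sample-size and replicate grids.

The design follows a two-stage rarefaction protocol: one random SNP
subset (default 3,000 loci) is drawn once per run and shared by every
replicate; each replicate then draws ``n`` individuals *without
replacement* from a population (individuals may recur across
replicates) and every statistic is evaluated on that subsample.

Stage 1 sweeps the replicate count ``x`` at a fixed sample size to find
the number of replicates beyond which cell means stabilise; stage 2
sweeps the sample size ``n`` at the chosen replicate count.  Cells of
the x-sweep are nested — the x=10 cell is the first 10 replicates of
the x=100 cell — which makes the sweep monotone in information and
bit-reproducible from a single master seed.

Replicate draws come from independent child streams spawned off the
master seed, keyed by (population or pair, grid value, replicate), so
any cell can be recomputed in isolation.  Within a replicate the same
subsample feeds all diversity parameters, as a field tool computing
Ae/Ho/uHe from one exported subsample would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from snpsample.genotype_io import GenotypeMatrix
from snpsample.popgen_stats import (
    UndefinedStatisticError,
    pairwise_fst,
    population_summary,
)

DIVERSITY_PARAMS = ("Ae", "Ho", "uHe")

#: TrajectoryTable column layout (long format).
TRAJECTORY_COLUMNS = ("parameter", "unit", "axis", "grid_value", "replicate", "value")


@dataclass(frozen=True)
class ResamplingDesign:
    """Grids and sizes for the two-stage resampling protocol.

    Defaults mirror a 10-individual-per-population study design:
    sample sizes 2..8, replicate counts 10..100 by 10, a single shared
    3,000-SNP subset, and the replicate-count sweep run at n = 3.
    """

    sample_size_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    replicate_grid: tuple[int, ...] = tuple(range(10, 101, 10))
    snp_subset_size: int = 3000
    fixed_n: int = 3
    seed: int = 0
    diversity_params: tuple[str, ...] = DIVERSITY_PARAMS
    fst_pairs: tuple[tuple[str, str], ...] | None = None  # None = all pairs

    def __post_init__(self) -> None:
        for name, grid in (
            ("sample_size_grid", self.sample_size_grid),
            ("replicate_grid", self.replicate_grid),
        ):
            if len(grid) < 1 or any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be strictly increasing: {grid}")
        if self.fixed_n not in self.sample_size_grid:
            raise ValueError(
                f"fixed_n {self.fixed_n} not in sample_size_grid {self.sample_size_grid}"
            )
        if self.snp_subset_size < 1:
            raise ValueError("snp_subset_size must be >= 1")
        unknown = set(self.diversity_params) - set(DIVERSITY_PARAMS)
        if unknown:
            raise ValueError(f"unknown diversity parameters: {sorted(unknown)}")

    @property
    def max_replicates(self) -> int:
        return self.replicate_grid[-1]


# ---------------------------------------------------------------------
# primitives


def subset_snps(loci: Sequence[str], L: int, rng: np.random.Generator) -> list[str]:
    """Uniform random subset of ``L`` locus ids, without replacement.

    Drawn once per pipeline run and shared by all replicates and grid
    points; order follows the original locus order for determinism.
    """
    if L > len(loci):
        raise ValueError(f"requested {L} SNPs but only {len(loci)} available")
    idx = np.sort(rng.choice(len(loci), size=L, replace=False))
    return [loci[i] for i in idx]


def draw_replicate(
    samples: Sequence[str], n: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``n`` distinct sample ids uniformly, without replacement."""
    if n > len(samples):
        raise ValueError(f"cannot draw {n} individuals from {len(samples)}")
    idx = rng.choice(len(samples), size=n, replace=False)
    chosen = [samples[i] for i in idx]
    assert len(set(chosen)) == n  # no individual twice within a replicate
    return chosen


def _child_rng(master: int, *key: int) -> np.random.Generator:
    """Independent stream for a (unit, grid value, replicate) cell."""
    return np.random.Generator(np.random.Philox(np.random.SeedSequence((master, *key))))


def _diversity_values(G_pop: GenotypeMatrix, sample_ids: Sequence[str]) -> dict[str, float]:
    stats = population_summary(G_pop.restrict_samples(sample_ids))
    return {"Ae": stats.mean_ae, "Ho": stats.mean_ho, "uHe": stats.mean_uhe}


# ---------------------------------------------------------------------
# sweeps


def _resolve_pairs(
    G: GenotypeMatrix, design: ResamplingDesign
) -> list[tuple[str, str]]:
    labels = G.population_labels()
    if design.fst_pairs is not None:
        for a, b in design.fst_pairs:
            if a not in labels or b not in labels:
                raise ValueError(f"FST pair ({a}, {b}) not present in matrix")
        return [tuple(p) for p in design.fst_pairs]
    return [
        (a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]
    ]


def _check_population_sizes(G: GenotypeMatrix, n: int) -> None:
    for label in G.population_labels():
        size = len(G.samples_in(label))
        if n > size:
            raise ValueError(
                f"population {label!r} has {size} individuals; cannot draw {n}"
            )


def run_replicate_sweep(G: GenotypeMatrix, design: ResamplingDesign) -> pd.DataFrame:
    """Stage 1: sweep the replicate count x at n = ``design.fixed_n``.

    Returns a long-format TrajectoryTable.  For the largest x in the
    grid one statistic value per replicate is computed; the cell for a
    smaller x is the first x replicates (nested prefixes), so every
    (parameter, grid value) cell holds exactly x rows.
    """
    _check_population_sizes(G, design.fixed_n)
    rng_subset = _child_rng(design.seed, 0)
    loci = subset_snps(G.loci, min(design.snp_subset_size, G.n_loci), rng_subset)
    G_sub = G.restrict_loci(loci)
    pairs = _resolve_pairs(G_sub, design)
    x_max = design.max_replicates
    n = design.fixed_n

    rows: list[tuple] = []
    pops = G_sub.population_labels()
    pop_matrices = {lab: G_sub.restrict_population(lab) for lab in pops}
    # per-replicate draws, reused as prefixes by every x cell
    draws: dict[str, list[list[str]]] = {}
    for pi, lab in enumerate(pops):
        draws[lab] = [
            draw_replicate(pop_matrices[lab].samples, n, _child_rng(design.seed, 1, pi, n, r))
            for r in range(x_max)
        ]
    div_values: dict[str, list[dict[str, float]]] = {
        lab: [_diversity_values(pop_matrices[lab], ids) for ids in draws[lab]]
        for lab in pops
    }
    fst_values: dict[tuple[str, str], list[float]] = {}
    for a, b in pairs:
        vals = []
        for r in range(x_max):
            vals.append(
                pairwise_fst(
                    pop_matrices[a].restrict_samples(draws[a][r]),
                    pop_matrices[b].restrict_samples(draws[b][r]),
                ).fst
            )
        fst_values[(a, b)] = vals

    for x in design.replicate_grid:
        for lab in pops:
            for r in range(x):
                vals = div_values[lab][r]
                for param in design.diversity_params:
                    rows.append((param, lab, "x", x, r, vals[param]))
        for a, b in pairs:
            for r in range(x):
                rows.append(("FST", f"{a}|{b}", "x", x, r, fst_values[(a, b)][r]))

    table = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    table.attrs["seed"] = design.seed
    table.attrs["snp_subset"] = loci
    table.attrs["fixed_n"] = n
    return table


def run_samplesize_sweep(
    G: GenotypeMatrix, design: ResamplingDesign, x_opt: int
) -> pd.DataFrame:
    """Stage 2: sweep the sample size n at ``x_opt`` replicates per cell.

    FST cells draw ``n`` individuals independently from each population
    of the pair per replicate.  The SNP subset is the same one stage 1
    uses (same master seed, same child stream).
    """
    if x_opt < 2:
        raise ValueError("x_opt must be >= 2 for summary statistics")
    _check_population_sizes(G, max(design.sample_size_grid))
    rng_subset = _child_rng(design.seed, 0)
    loci = subset_snps(G.loci, min(design.snp_subset_size, G.n_loci), rng_subset)
    G_sub = G.restrict_loci(loci)
    pairs = _resolve_pairs(G_sub, design)
    pops = G_sub.population_labels()
    pop_matrices = {lab: G_sub.restrict_population(lab) for lab in pops}

    rows: list[tuple] = []
    for n in design.sample_size_grid:
        draws: dict[str, list[list[str]]] = {}
        for pi, lab in enumerate(pops):
            draws[lab] = [
                draw_replicate(
                    pop_matrices[lab].samples, n, _child_rng(design.seed, 2, pi, n, r)
                )
                for r in range(x_opt)
            ]
        for lab in pops:
            for r in range(x_opt):
                vals = _diversity_values(pop_matrices[lab], draws[lab][r])
                for param in design.diversity_params:
                    rows.append((param, lab, "n", n, r, vals[param]))
        for a, b in pairs:
            for r in range(x_opt):
                fst = pairwise_fst(
                    pop_matrices[a].restrict_samples(draws[a][r]),
                    pop_matrices[b].restrict_samples(draws[b][r]),
                ).fst
                rows.append(("FST", f"{a}|{b}", "n", n, r, fst))

    table = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    table.attrs["seed"] = design.seed
    table.attrs["snp_subset"] = loci
    table.attrs["x_opt"] = x_opt
    return table


def write_trajectory(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
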