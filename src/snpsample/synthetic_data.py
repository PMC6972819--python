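"""Balding-Nichols genotype simulator with ground-truth records.

Populations diverge from a shared ancestral allele frequency p under
pure drift of magnitude F: each population's frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F*p*(1-p).
Genotypes are drawn per individual with an optional within-population
inbreeding coefficient F_IS: with probability F_IS the two alleles are
identical by descent (dosage = 2*Bernoulli(p_pop)), otherwise the draw
is the Hardy-Weinberg Binomial(2, p_pop).  This keeps allele
frequencies unchanged while depressing heterozygotes to
P(het) = 2pq(1-F_IS), the heterozygote deficit that inbred or
substructured field populations show (observed Ho below uHe).  Missing
calls are masked uniformly (MCAR) at a configurable rate.

For two populations at equal divergence F the Nei-style frequency FST
used downstream converges to F/(2-F) as loci grow, which gives closed-
form recovery targets for tests.  Presets emulate a low-heterozygosity
whitefly-like study system: 10 diploid individuals per population,
thousands of biallelic SNPs, within-population uHe around 0.06-0.12,
and pairwise FST near 0.08 (preset ``Q1``, weak divergence) or 0.35
(preset ``Q2``, strong divergence).  Low heterozygosity comes from a
rare-allele-skewed ancestral prior (Beta with most mass at low minor
allele frequency, as in an empirical RAD site-frequency spectrum)
truncated at a MAF floor of 0.01, mirroring the MAF filter genotype
panels are typically subjected to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from snpsample.genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Balding-Nichols simulation.

    ``fst`` holds one divergence parameter F per population (0 <= F < 1);
    ``ancestral_prior`` is either ``("beta", a, b)`` or
    ``("uniform", lo, hi)``; draws below ``maf_floor`` (or above its
    mirror) are rejected and redrawn.
    """

    n_populations: int = 2
    n_per_population: int = 10
    n_loci: int = 3000
    fst: tuple[float, ...] = (0.2, 0.2)
    ancestral_prior: tuple = ("beta", 0.25, 0.25)
    maf_floor: float = 0.01
    missing_rate: float = 0.1
    inbreeding: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_populations < 1 or self.n_per_population < 1:
            raise ValueError("need at least one population and one individual")
        if len(self.fst) != self.n_populations:
            raise ValueError(
                f"{len(self.fst)} F values for {self.n_populations} populations"
            )
        for f in self.fst:
            if not (0.0 <= f < 1.0):
                raise ValueError(f"F must be in [0, 1), got {f} (F=1 is degenerate)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.inbreeding < 1.0):
            raise ValueError("inbreeding must be in [0, 1)")
        if not (0.0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in [0, 0.5)")
        if self.ancestral_prior[0] not in ("beta", "uniform"):
            raise ValueError(f"unknown prior {self.ancestral_prior[0]!r}")

    @property
    def population_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]


@dataclass
class TruthRecord:
    """Ground truth of one simulation, for recovery tests."""

    ancestral: np.ndarray = field(repr=False)
    population_freqs: dict[str, np.ndarray] = field(repr=False)
    fst: dict[str, float] = field(default_factory=dict)

    def expected_pairwise_fst(self, pop_a: str, pop_b: str) -> float:
        """Model expectation of the downstream Nei FST for a pair.

        For divergences F_a, F_b the per-locus expectations are
        Hs = 2pq(1 - Fbar) and Ht = 2pq(1 - Fbar/2) with
        Fbar = (F_a + F_b)/2; the p-dependence cancels in the ratio of
        locus means, giving FST -> Fbar / (2 - Fbar).
        """
        fbar = 0.5 * (self.fst[pop_a] + self.fst[pop_b])
        return expected_nei_fst(fbar)

    def nei_fst_of_truth(self, pop_a: str, pop_b: str) -> float:
        """Nei FST computed from the realized true frequencies."""
        pa = self.population_freqs[pop_a]
        pb = self.population_freqs[pop_b]
        hs = 0.5 * (2 * pa * (1 - pa) + 2 * pb * (1 - pb))
        pbar = 0.5 * (pa + pb)
        ht = 2 * pbar * (1 - pbar)
        return float((ht.mean() - hs.mean()) / ht.mean())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fst": self.fst,
            "ancestral": self.ancestral.round(6).tolist(),
            "population_freqs": {
                k: v.round(6).tolist() for k, v in self.population_freqs.items()
            },
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def expected_nei_fst(f: float) -> float:
    """Large-locus limit of the Nei FST between two populations at F = f."""
    return f / (2.0 - f)


# ---------------------------------------------------------------------


def _draw_ancestral(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.ancestral_prior[0]
    lo, hi = cfg.maf_floor, 1.0 - cfg.maf_floor
    p = np.empty(cfg.n_loci)
    todo = np.ones(cfg.n_loci, dtype=bool)
    while todo.any():  # rejection sampling against the MAF floor
        k = int(todo.sum())
        if kind == "beta":
            draw = rng.beta(cfg.ancestral_prior[1], cfg.ancestral_prior[2], size=k)
        else:
            a, b = cfg.ancestral_prior[1], cfg.ancestral_prior[2]
            draw = rng.uniform(a, b, size=k)
        p[todo] = draw
        todo &= (p < lo) | (p > hi)
    return p


def simulate_frequencies(cfg: SimulationConfig) -> TruthRecord:
    """Draw ancestral and per-population allele frequencies.

    With F = 0 a population's frequencies equal the ancestral ones
    exactly (no-drift limit, no Beta draw involved).
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((cfg.seed, 0))))
    ancestral = _draw_ancestral(cfg, rng)
    freqs: dict[str, np.ndarray] = {}
    fst: dict[str, float] = {}
    for label, f in zip(cfg.population_labels, cfg.fst):
        if f == 0.0:
            freqs[label] = ancestral.copy()
        else:
            scale = (1.0 - f) / f
            freqs[label] = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)
        fst[label] = f
    return TruthRecord(ancestral=ancestral, population_freqs=freqs, fst=fst)


def simulate_genotypes(truth: TruthRecord, cfg: SimulationConfig) -> GenotypeMatrix:
    """HWE genotypes from the truth frequencies, with MCAR missingness."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((cfg.seed, 1))))
    samples: list[str] = []
    populations: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for label in cfg.population_labels:
        p = truth.population_freqs[label]
        shape = (cfg.n_per_population, cfg.n_loci)
        block = rng.binomial(2, p, size=shape).astype(np.int8)
        if cfg.inbreeding > 0.0:
            # identical-by-descent draws replace HWE draws per call
            ibd = rng.random(shape) < cfg.inbreeding
            block[ibd] = (2 * rng.binomial(1, p, size=shape).astype(np.int8))[ibd]
        if cfg.missing_rate > 0.0:
            mask = rng.random((cfg.n_per_population, cfg.n_loci)) < cfg.missing_rate
            block[mask] = MISSING
        blocks.append(block)
        for i in range(cfg.n_per_population):
            sid = f"{label}_ind{i + 1:02d}"
            samples.append(sid)
            populations[sid] = label
    loci = [f"snp{j + 1:05d}" for j in range(cfg.n_loci)]
    return GenotypeMatrix(
        samples=samples,
        loci=loci,
        populations=populations,
        calls=np.vstack(blocks),
    )


def simulate(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Frequencies then genotypes, both derived from ``cfg.seed``."""
    truth = simulate_frequencies(cfg)
    return simulate_genotypes(truth, cfg), truth


# ---------------------------------------------------------------------
# study presets

# Divergence chosen so the two-population Nei FST limit F/(2-F) lands on
# the preset's target; the skewed ancestral Beta(a, b), truncated at the
# MAF floor, sets within-population heterozygosity 2pq(1-F) into the
# 0.06-0.12 band (a symmetric U-shaped Beta cannot reach it once the
# near-fixed mass is cut away by the floor).
_PRESETS: dict[str, SimulationConfig] = {
    # weak within-clade divergence, target FST ~ 0.08, uHe ~ 0.10
    "Q1": SimulationConfig(
        n_populations=2,
        n_per_population=10,
        n_loci=3000,
        fst=(0.1444, 0.1444),
        ancestral_prior=("beta", 0.5, 10.5),
        maf_floor=0.01,
        missing_rate=0.1,
        inbreeding=0.2,
    ),
    # strong between-clade divergence, target FST ~ 0.35, uHe ~ 0.07
    "Q2": SimulationConfig(
        n_populations=2,
        n_per_population=10,
        n_loci=3000,
        fst=(0.5138, 0.5138),
        ancestral_prior=("beta", 0.5, 7.5),
        maf_floor=0.01,
        missing_rate=0.1,
        inbreeding=0.2,
    ),
}

#: Acceptance bands for preset realizations (checked, re-drawn on miss).
_PRESET_BANDS: dict[str, dict[str, tuple[float, float]]] = {
    "Q1": {"fst": (0.04, 0.12), "uhe": (0.04, 0.15)},
    "Q2": {"fst": (0.25, 0.45), "uhe": (0.04, 0.15)},
}


def preset_config(preset: str, seed: int = 0, **overrides) -> SimulationConfig:
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    return replace(_PRESETS[preset], seed=seed, **overrides)


def simulate_study(
    preset: str, seed: int = 0, max_retries: int = 10, **overrides
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a two-population study matching a preset's target bands.

    The realized pairwise Nei FST (from genotypes) and each
    population's mean uHe are checked against the preset's bands; a
    miss triggers a redraw with a derived seed, up to ``max_retries``
    attempts, after which the realized values are reported in the
    error.  Sampling noise at 10 individuals x 3,000 loci is small, so
    retries are rare.
    """
    from snpsample.popgen_stats import pairwise_fst, population_summary

    bands = _PRESET_BANDS[preset] if preset in _PRESET_BANDS else None
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    last: dict[str, float] = {}
    for attempt in range(max_retries):
        cfg = preset_config(preset, seed=_derive_seed(seed, attempt), **overrides)
        G, truth = simulate(cfg)
        fst = pairwise_fst(
            G.restrict_population("pop1"), G.restrict_population("pop2")
        ).fst
        uhes = [
            population_summary(G, label).mean_uhe for label in cfg.population_labels
        ]
        last = {"fst": fst, "uhe_min": min(uhes), "uhe_max": max(uhes)}
        ok = bands is None or (
            bands["fst"][0] <= fst <= bands["fst"][1]
            and all(bands["uhe"][0] <= u <= bands["uhe"][1] for u in uhes)
        )
        if ok:
            return G, truth
    raise RuntimeError(
        f"preset {preset!r} missed its target bands after {max_retries} draws; "
        f"last realization: {last}"
    )


def _derive_seed(seed: int, attempt: int) -> int:
    # stable, collision-free, and below 2**31 for downstream consumers
    return int((seed * 1009 + attempt * 7919 + 17) % (2**31 - 1))
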