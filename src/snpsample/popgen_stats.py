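"""Diversity and differentiation statistics, GenAlEx conventions.

Per biallelic locus with alternate-allele frequency ``p`` (``q = 1-p``)
estimated from the ``n`` genotyped individuals:

* number of effective alleles  ``Ae = 1 / (p^2 + q^2)``
* observed heterozygosity      ``Ho = #het / n``
* expected heterozygosity      ``He = 2pq``
* unbiased expected het.       ``uHe = (2n / (2n - 1)) * He``

Pairwise differentiation between populations A and B is the Nei-style
frequency-based FST: per locus ``Hs = (He_A + He_B)/2`` and
``Ht = 2 * pbar * (1 - pbar)`` with ``pbar = (p_A + p_B)/2``, aggregated
as a ratio of unweighted locus means, ``FST = (mean Ht - mean Hs) / mean
Ht``.  No sample-size correction enters Ht or Hs.  A Weir & Cockerham
theta estimator is available for sensitivity analysis via
``pairwise_fst(..., method="wc")``.

All statistics are invariant under swapping allele labels (p <-> 1-p).
Loci with no genotyped individual in a population are dropped from that
population's summary; for FST a locus must be genotyped in both
populations to contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from snpsample.genotype_io import MISSING, GenotypeMatrix


class UndefinedStatisticError(ValueError):
    """A statistic has no defined value (e.g. all calls missing)."""


# ---------------------------------------------------------------------
# scalar / per-column primitives


def allele_frequency(column: np.ndarray) -> tuple[float, int]:
    """Alternate-allele frequency and count of genotyped individuals.

    ``p = (sum of dosages) / (2 * n_typed)`` over non-missing calls.
    """
    column = np.asarray(column)
    typed = column[column != MISSING]
    if typed.size == 0:
        raise UndefinedStatisticError("all calls missing: allele frequency undefined")
    return float(typed.sum()) / (2 * typed.size), int(typed.size)


def effective_alleles(p: float | np.ndarray) -> float | np.ndarray:
    """Ae = 1 / (p^2 + q^2); 1 for a monomorphic locus, 2 at p = 0.5."""
    p = np.asarray(p, dtype=float)
    out = 1.0 / (p**2 + (1.0 - p) ** 2)
    return float(out) if out.ndim == 0 else out


def observed_het(column: np.ndarray) -> float:
    """Fraction of genotyped individuals that are heterozygous."""
    column = np.asarray(column)
    typed = column[column != MISSING]
    if typed.size == 0:
        raise UndefinedStatisticError("all calls missing: Ho undefined")
    return float((typed == 1).sum()) / typed.size


def expected_het(p: float | np.ndarray) -> float | np.ndarray:
    """He = 2pq, the Hardy-Weinberg heterozygote expectation."""
    p = np.asarray(p, dtype=float)
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def unbiased_expected_het(
    p: float | np.ndarray, n_typed: int | np.ndarray
) -> float | np.ndarray:
    """uHe = (2n / (2n - 1)) * 2pq with the locus-specific n."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n_typed, dtype=float)
    if np.any(n < 1):
        raise UndefinedStatisticError("uHe needs at least one genotyped individual")
    out = (2.0 * n / (2.0 * n - 1.0)) * 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------
# vectorised per-locus frequencies


def _column_freqs(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (p, n_typed) for a calls matrix; p is nan where untyped."""
    typed = calls != MISSING
    n_typed = typed.sum(axis=0).astype(float)
    dosage_sum = np.where(typed, calls, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_typed > 0, dosage_sum / (2.0 * n_typed), np.nan)
    return p, n_typed


# ---------------------------------------------------------------------
# population summary


@dataclass
class PopulationStats:
    """Per-locus and mean diversity statistics for one population."""

    population: str
    loci: list[str]
    p: np.ndarray = field(repr=False)
    n_typed: np.ndarray = field(repr=False)
    ae: np.ndarray = field(repr=False)
    ho: np.ndarray = field(repr=False)
    he: np.ndarray = field(repr=False)
    uhe: np.ndarray = field(repr=False)
    mean_ae: float = 0.0
    mean_ho: float = 0.0
    mean_he: float = 0.0
    mean_uhe: float = 0.0
    n_loci_dropped: int = 0

    def means(self) -> dict[str, float]:
        return {
            "Ae": self.mean_ae,
            "Ho": self.mean_ho,
            "He": self.mean_he,
            "uHe": self.mean_uhe,
        }


def population_summary(G: GenotypeMatrix, population: str | None = None) -> PopulationStats:
    """Diversity statistics for one population.

    ``G`` may already be restricted to a single population (then
    ``population`` is optional).  Loci with zero genotyped individuals
    are excluded from the means and counted in ``n_loci_dropped``;
    means across loci are unweighted.
    """
    if population is not None:
        G = G.restrict_population(population)
        label = population
    else:
        labels = G.population_labels()
        if len(labels) != 1:
            raise ValueError(
                f"matrix holds populations {labels}; name one to summarise"
            )
        label = labels[0]
    if G.n_samples == 0:
        raise UndefinedStatisticError(f"population {label!r} has no samples")

    p, n_typed = _column_freqs(G.calls)
    defined = n_typed > 0
    if not defined.any():
        raise UndefinedStatisticError(
            f"population {label!r}: no locus with a genotyped individual"
        )
    typed_mask = G.calls != MISSING
    het_counts = ((G.calls == 1) & typed_mask).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(defined, het_counts / n_typed, np.nan)
        ae = np.where(defined, 1.0 / (p**2 + (1.0 - p) ** 2), np.nan)
        he = np.where(defined, 2.0 * p * (1.0 - p), np.nan)
        uhe = np.where(
            n_typed > 0, (2.0 * n_typed / (2.0 * n_typed - 1.0)) * he, np.nan
        )
    return PopulationStats(
        population=label,
        loci=list(G.loci),
        p=p,
        n_typed=n_typed,
        ae=ae,
        ho=ho,
        he=he,
        uhe=uhe,
        mean_ae=float(np.nanmean(ae)),
        mean_ho=float(np.nanmean(ho)),
        mean_he=float(np.nanmean(he)),
        mean_uhe=float(np.nanmean(uhe)),
        n_loci_dropped=int((~defined).sum()),
    )


# ---------------------------------------------------------------------
# pairwise FST


@dataclass
class FstResult:
    """Nei-style pairwise FST between two populations."""

    pair: tuple[str, str]
    fst: float
    ht_bar: float
    hs_bar: float
    n_loci_used: int
    n_loci_dropped: int
    method: str = "nei"
    per_locus_ht: np.ndarray | None = field(default=None, repr=False)
    per_locus_hs: np.ndarray | None = field(default=None, repr=False)


def pairwise_fst(
    G_A: GenotypeMatrix,
    G_B: GenotypeMatrix,
    method: str = "nei",
    keep_per_locus: bool = False,
) -> FstResult:
    """Pairwise FST between two single-population matrices.

    Both matrices must share the same locus list.  Loci undefined
    (all-missing) in either population are dropped pairwise.  With
    ``method="nei"`` (default) the frequency-based ratio-of-means
    estimator described in the module docstring is used; loci
    monomorphic across the pooled pair are allowed and pull the ratio
    toward the genome-wide mean.  ``method="wc"`` computes Weir &
    Cockerham's theta (ratio of summed variance components) instead.
    """
    if G_A.loci != G_B.loci:
        raise ValueError("populations must share an identical locus list")
    label_a = G_A.population_labels()[0]
    label_b = G_B.population_labels()[0]

    p_a, n_a = _column_freqs(G_A.calls)
    p_b, n_b = _column_freqs(G_B.calls)
    defined = (n_a > 0) & (n_b > 0)
    n_dropped = int((~defined).sum())
    if not defined.any():
        raise UndefinedStatisticError("no locus genotyped in both populations")

    if method == "nei":
        he_a = 2.0 * p_a[defined] * (1.0 - p_a[defined])
        he_b = 2.0 * p_b[defined] * (1.0 - p_b[defined])
        hs = 0.5 * (he_a + he_b)
        pbar = 0.5 * (p_a[defined] + p_b[defined])
        ht = 2.0 * pbar * (1.0 - pbar)
        ht_bar = float(ht.mean())
        hs_bar = float(hs.mean())
        if ht_bar == 0.0:
            raise UndefinedStatisticError(
                "mean Ht is zero (no variation anywhere): FST undefined"
            )
        fst = (ht_bar - hs_bar) / ht_bar
        return FstResult(
            pair=(label_a, label_b),
            fst=float(fst),
            ht_bar=ht_bar,
            hs_bar=hs_bar,
            n_loci_used=int(defined.sum()),
            n_loci_dropped=n_dropped,
            method="nei",
            per_locus_ht=ht if keep_per_locus else None,
            per_locus_hs=hs if keep_per_locus else None,
        )
    if method == "wc":
        fst = _weir_cockerham_theta(
            p_a[defined], n_a[defined], _het_rate(G_A.calls)[defined],
            p_b[defined], n_b[defined], _het_rate(G_B.calls)[defined],
        )
        return FstResult(
            pair=(label_a, label_b),
            fst=float(fst),
            ht_bar=float("nan"),
            hs_bar=float("nan"),
            n_loci_used=int(defined.sum()),
            n_loci_dropped=n_dropped,
            method="wc",
        )
    raise ValueError(f"unknown FST method {method!r}")


def _het_rate(calls: np.ndarray) -> np.ndarray:
    typed = calls != MISSING
    n = typed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, ((calls == 1) & typed).sum(axis=0) / n, np.nan)


def _weir_cockerham_theta(
    p1: np.ndarray, n1: np.ndarray, h1: np.ndarray,
    p2: np.ndarray, n2: np.ndarray, h2: np.ndarray,
) -> float:
    """Weir & Cockerham (1984) theta for two populations, summed over loci.

    Variance components a (among populations), b (among individuals
    within populations) and c (within individuals) follow the standard
    two-level formulation with r = 2 subpopulations; theta is
    sum(a) / sum(a + b + c) over loci.
    """
    r = 2.0
    n_bar = (n1 + n2) / r
    # coefficient of variation of sample sizes
    nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    pq = p_bar * (1.0 - p_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / nc) * (
            s2 - (pq - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            pq - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if den == 0.0:
        raise UndefinedStatisticError("WC theta undefined: zero total variance")
    return num / den


def fst_matrix(G: GenotypeMatrix, method: str = "nei") -> dict[tuple[str, str], FstResult]:
    """All pairwise FST results between the populations of ``G``."""
    labels = G.population_labels()
    out: dict[tuple[str, str], FstResult] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            out[(a, b)] = pairwise_fst(
                G.restrict_population(a), G.restrict_population(b), method=method
            )
    return out
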