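# Methods

## Scope and model

`snpsample` treats a genotype matrix — diploid individuals × biallelic
SNP loci, dosage-coded 0/1/2 with an explicit missing sentinel and a
population label per individual — as the unit of analysis. Everything
downstream of SNP calling is in scope: post-call locus filtering,
GenAlEx-convention diversity and differentiation statistics, the
individual-resampling design, and the Δ*K* decision rule. Read
processing, mapping and SNP calling are upstream of the matrix and out
of scope.

## Locus filtering

Four retention rules run in a fixed order on per-locus annotations
(pooled MAF, tag membership, observed allele count, call rate):

1. MAF < `maf_min` (default 0.01) — removes near-monomorphic calls most
   likely to be genotyping error; a locus with no non-missing calls has
   undefined MAF and auto-fails here;
2. more than `max_snps_per_tag` (default 2) SNPs on one restriction
   tag — clustered variation on a short tag suggests paralogy;
3. observed allele count outside {2, 3} — with dosage-coded biallelic
   input only the monomorphic case is reachable;
4. call rate not strictly above `call_rate_min` (default 0.8).

A locus failing several rules is attributed to the first; attribution
only affects the report, never the surviving set, and per-rule counts
plus survivors always partition the input. Filtering is idempotent. MAF
is pooled across all samples in the matrix by default; pass a
population subset to `compute_annotations` for per-population
filtering.

## Statistics

Per locus with alt-allele frequency *p̂* = (Σ dosages)/(2*n*) over the
*n* genotyped individuals: *Ae* = 1/(*p̂*² + *q̂*²), *Ho* = #het/*n*,
*He* = 2*p̂q̂*, *uHe* = (2*n*/(2*n* − 1))·*He* with the locus-specific
*n*. Matrix-level values are unweighted means over loci with at least
one genotyped individual; dropped-locus counts are retained.

Pairwise FST is the Nei-style frequency-based estimator: per locus
*H*<sub>S</sub> = (*He*<sub>A</sub> + *He*<sub>B</sub>)/2 and
*H*<sub>T</sub> = 2*p̄*(1 − *p̄*) with the unweighted mean frequency
*p̄*; the matrix-level value is the ratio of locus means, (mean
*H*<sub>T</sub> − mean *H*<sub>S</sub>)/mean *H*<sub>T</sub>. No
sample-size correction enters *H*<sub>S</sub> or *H*<sub>T</sub> — the
small-sample correction applies only to the diversity parameter *uHe*.
Consequences worth knowing: at small per-population *n* the estimator
is biased upward (sampling variance of *p̂* inflates *H*<sub>T</sub>
relative to *H*<sub>S</sub>; at *n* = 10 and true divergence 0.08 the
realized value sits near 0.10–0.11), and loci monomorphic across the
pooled pair pull the ratio toward the panel-wide mean. Both behaviours
belong to the estimator being studied, so they are left intact; a Weir
& Cockerham θ (two-population variance-components form) is available
via `method="wc"` for sensitivity checks, not as the default. Loci
undefined in either population are dropped pairwise.

All statistics are invariant under swapping allele labels, so the
choice of reference allele in the CSV dialect (lexicographically
smaller code) cannot affect results; this is property-tested.

## Resampling design

One SNP subset (default 3,000 loci) is drawn uniformly without
replacement once per run and shared by every replicate and grid point.
Each replicate draws *n* individuals without replacement from one
population — no individual twice within a replicate, individuals free
to recur across replicates — and all three diversity parameters are
computed from that one subsample, as a practitioner exporting a
subsample to GenAlEx would. FST replicates draw *n* individuals
independently from each population of the pair.

Stage 1 (replicate sweep) fixes *n* (default 3) and computes one value
per replicate up to the largest grid entry (default 100); the cell for
a smaller *x* is the first *x* replicates. This nesting makes the sweep
monotone in information and the whole table bit-reproducible; per-cell
distributions are unaffected because replicates are i.i.d. Stage 2
(sample-size sweep) fixes *x* at the stage-1 optimum and draws fresh
replicates per *n* ∈ {2..8}.

Randomness: a master seed spawns an independent Philox stream per
(population-or-pair, grid value, replicate), so any cell can be
recomputed in isolation. Per-replicate statistics never drop a
replicate: a locus all-missing in a subsample is dropped locus-wise
inside that replicate's summary and the replicate count stays exact.

## Summaries and the Δ*K* rule

Each (parameter, grid value) cell is summarised by the mean, sample SD
(ddof = 1) and a Student-*t* 95% CI of the mean (normal-approximation
CIs behind a flag). The plateau statistic is

  Δ*K*(*k*) = |*m*(*k*₊) − 2·*m*(*k*) + *m*(*k*₋)| / sd(*k*)

at interior grid points, computed on grid index (both default grids are
equally spaced, so the argmax is unaffected). A cell with sd = 0 maps a
nonzero second difference to +∞ and a zero one to 0. The selected
optimum is the argmax; ties break toward the smaller grid value because
minimality is the point; an all-zero (flat) curve returns the smallest
interior value with a flag. The two grid endpoints have no Δ*K* value,
so an optimum can only be an interior grid point.

`determine()` runs stage 1, takes the most conservative (maximum)
per-series replicate optimum as *x*, runs stage 2 at that *x*, and
reports per-series sample-size optima plus the conservative maximum. It
also cross-checks, per series, whether the chosen *n*'s CI overlaps the
largest-*n* cell's CI — Δ*K* peak location and CI overlap are two
different lenses on "no further change" and are reported side by side
rather than merged.

## Synthetic data

The generator is a Balding–Nichols construction: ancestral frequency
*p* per locus from a configurable prior; population frequency from
Beta(*p*(1 − *F*)/*F*, (1 − *p*)(1 − *F*)/*F*), mean *p*, variance
*F·p*(1 − *p*); *F* = 0 short-circuits to the ancestral value and
*F* = 1 is rejected as degenerate. Genotypes are per-individual draws
with an inbreeding coefficient *F*<sub>IS</sub>: with probability
*F*<sub>IS</sub> the two alleles are identical by descent (dosage
2·Bernoulli(*p*)), otherwise Binomial(2, *p*). Missing calls are masked
uniformly at random (MCAR). For two populations at drift *F* the
downstream Nei FST converges to *F*/(2 − *F*) as loci grow — the
closed-form recovery target used in tests.

Two presets emulate a whitefly-like invasion-genomics study system (10
diploid individuals per population, 3,000 SNPs, ≤20% missingness per
SNP):

| preset | drift *F* | FST limit | ancestral prior | uHe ≈ | Ho ≈ |
|--------|-----------|-----------|-----------------|-------|------|
| Q1 (weak, within-clade) | 0.1444 | 0.0778 | Beta(0.5, 10.5), MAF ≥ 0.01 | 0.10 | 0.08 |
| Q2 (strong, between-clade) | 0.5138 | 0.3457 | Beta(0.5, 7.5), MAF ≥ 0.01 | 0.07 | 0.06 |

Design choices behind the presets:

- **Rare-allele-skewed prior.** The target heterozygosity band
  (uHe ≈ 0.06–0.12) is far below the ~0.33 of a uniform frequency
  prior. A symmetric U-shaped Beta cannot reach it either once the MAF
  floor is applied: as the shape parameter → 0 the truncated density
  tends to ∝ 1/(*pq*), whose mean 2*pq* is ≈ 0.21 — a hard lower bound.
  The presets therefore use Beta(0.5, *b*) priors (most mass at low
  minor-allele frequency, like an empirical RAD site-frequency
  spectrum after MAF filtering), with *b* calibrated numerically
  against the truncated expectation so that (1 − *F*)·E[2*pq*] lands on
  the preset's heterozygosity target.
- **Inbreeding 0.2.** Field populations of the emulated system show a
  marked heterozygote deficit (Ho about 20% below uHe). The deficit is
  not cosmetic: under exact HWE the subsampled uHe trajectory is flat
  in expectation (the (2*n*/(2*n* − 1)) correction makes uHe unbiased),
  so the Δ*K* peak would sit on Monte-Carlo noise. With
  *F*<sub>IS</sub> > 0 the expected trajectory bends like
  uHe·(1 − *F*<sub>IS</sub>/(2*n*)), concentrating genuine curvature at
  small *n* — the feature the decision rule is designed to detect.
  Preset value 0.2 is derived from the observed Ho/uHe ratio of the
  emulated system (≈ 1 − 0.061/0.077).
- **Band-checked draws.** `simulate_study` verifies the realized FST
  and uHe against the preset's bands (Q1 FST ∈ [0.04, 0.12], Q2
  ∈ [0.25, 0.45], uHe ∈ [0.04, 0.15]) and redraws with a derived seed
  up to a bounded retry count; at 3,000 loci the realization noise is
  small and retries are rare.

What the generator does **not** emulate: linkage between SNPs (loci are
independent, so replicate SDs are mildly optimistic relative to real
RAD panels with co-located SNPs), selection, mutation, non-random
missingness, and genotyping error. Passing tests therefore show the
pipeline behaves correctly under drift-dominated divergence with
independent loci; they do not certify sample-size recommendations for
data whose error structure differs materially.

## Problem sizes and numerics

The default analysis scale mirrors the emulated study (10 individuals
per population, 3,000-SNP subsets, *x* ≤ 100, *n* ∈ {2..8}) and runs in
about a second per two-population study; test and acceptance runs use
10 seeded repetitions of that scale, and recovery experiments use up to
50–60 individuals per population and 3,000–4,000 loci. All statistics
are computed in double precision with no display rounding internally;
reported tables round to 3–4 decimals. Degenerate inputs are contracts,
not silent NaNs: all-missing loci raise or are flagged and excluded,
zero total heterozygosity makes FST undefined and says so, and grids
must be strictly increasing with at least three points for Δ*K*.

## Known limitations

- The Δ*K* statistic divides by the cell SD, which shrinks as *n* grows;
  on trajectories with no real curvature the peak tends to drift toward
  large *n* (noise amplification). The CI-overlap cross-check in the
  report is the guard: a Δ*K* peak with overlapping CIs means "flat".
- The frequency-based FST carries its small-sample inflation by design
  (it is the estimator whose sample-size behaviour is under study);
  use `method="wc"` to gauge the difference.
- Resampling from 10 individuals produces heavily overlapping
  replicates at larger *n*; replicate SDs at *n* near the population
  size understate between-sample variability in nature.
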