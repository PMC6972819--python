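"""Post-call SNP retention rules.

Four rules are applied in a fixed order to a genotype matrix plus
per-locus annotations:

a. drop loci with minor allele frequency below a floor (default 0.01);
b. drop every SNP on a tag carrying more than ``max_snps_per_tag`` SNPs
   (default 2) — co-located SNPs on one restriction tag are suspect;
c. drop loci whose observed allele count is outside {2, 3} (for dosage
   data this reduces to dropping monomorphic loci);
d. keep only loci genotyped in strictly more than ``call_rate_min`` of
   the individuals (default 0.8).

A locus failing several rules is attributed to the first rule it fails,
so per-rule removal counts plus survivors always sum to the input locus
count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from snpsample.genotype_io import MISSING, GenotypeMatrix

RULE_ORDER = ("maf", "snps_per_tag", "n_alleles", "call_rate")


@dataclass(frozen=True)
class LocusAnnotation:
    """Per-SNP summary used by the retention rules.

    ``maf`` is the pooled minor allele frequency over all samples,
    ``call_rate`` the fraction of non-missing calls, ``n_alleles`` the
    number of distinct alleles observed.  A locus with zero non-missing
    calls has undefined MAF (``nan``) and is auto-failed.
    """

    locus: str
    tag: str
    n_alleles: int
    maf: float
    call_rate: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_alleles <= 4):
            raise ValueError(f"{self.locus}: n_alleles {self.n_alleles} out of range")
        if not math.isnan(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.locus}: maf {self.maf} outside [0, 0.5]")
        if not (0.0 <= self.call_rate <= 1.0):
            raise ValueError(f"{self.locus}: call_rate {self.call_rate} outside [0, 1]")

    @property
    def undefined(self) -> bool:
        return math.isnan(self.maf)


@dataclass(frozen=True)
class FilterThresholds:
    maf_min: float = 0.01
    max_snps_per_tag: int = 2
    call_rate_min: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 1.0):
            raise ValueError(f"maf_min {self.maf_min} outside [0, 1]")
        if not (0.0 <= self.call_rate_min <= 1.0):
            raise ValueError(f"call_rate_min {self.call_rate_min} outside [0, 1]")
        if self.max_snps_per_tag < 1:
            raise ValueError("max_snps_per_tag must be >= 1")


@dataclass
class FilterReport:
    """Removal counts per rule, in application order."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    removed_loci: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_survivors(self) -> int:
        return self.n_input - self.n_removed

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "removed": self.removed,
                "n_survivors": self.n_survivors,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rule\tn_removed\n")
            for rule in RULE_ORDER:
                fh.write(f"{rule}\t{self.removed.get(rule, 0)}\n")
            fh.write(f"survivors\t{self.n_survivors}\n")


def compute_annotations(
    G: GenotypeMatrix,
    tagmap: Mapping[str, str] | None = None,
    populations: Sequence[str] | None = None,
) -> list[LocusAnnotation]:
    """Annotate every locus with tag, allele count, MAF and call rate.

    MAF is pooled across all samples of ``G`` (restrict the matrix first,
    or pass ``populations``, for per-population annotation).  ``tagmap``
    maps locus id -> tag id; the identity map is assumed when omitted,
    i.e. one SNP per tag.
    """
    if populations is not None:
        keep = [s for s in G.samples if G.populations[s] in set(populations)]
        G = G.restrict_samples(keep)
    if tagmap is None:
        tagmap = {}
    annotations = []
    calls = G.calls
    for j, locus in enumerate(G.loci):
        col = calls[:, j]
        typed = col[col != MISSING]
        call_rate = typed.size / col.size if col.size else 0.0
        if typed.size == 0:
            annotations.append(
                LocusAnnotation(locus, tagmap.get(locus, locus), 0, float("nan"), 0.0)
            )
            continue
        p = float(typed.sum()) / (2 * typed.size)
        n_alleles = 1 if p in (0.0, 1.0) else 2
        annotations.append(
            LocusAnnotation(
                locus=locus,
                tag=tagmap.get(locus, locus),
                n_alleles=n_alleles,
                maf=min(p, 1.0 - p),
                call_rate=call_rate,
            )
        )
    return annotations


def apply_filters(
    G: GenotypeMatrix,
    annotations: Sequence[LocusAnnotation],
    thresholds: FilterThresholds | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply retention rules a-d in order; return survivors and a report.

    ``annotations`` must be aligned 1:1 with ``G.loci``.  A locus with
    undefined MAF (all calls missing) fails rule (a) automatically.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    if len(annotations) != G.n_loci:
        raise ValueError(
            f"{len(annotations)} annotations for {G.n_loci} loci; must align"
        )
    for ann, locus in zip(annotations, G.loci):
        if ann.locus != locus:
            raise ValueError(f"annotation {ann.locus!r} misaligned with locus {locus!r}")

    tag_counts: dict[str, int] = {}
    for ann in annotations:
        tag_counts[ann.tag] = tag_counts.get(ann.tag, 0) + 1

    report = FilterReport(n_input=G.n_loci)
    report.removed = {rule: 0 for rule in RULE_ORDER}
    report.removed_loci = {rule: [] for rule in RULE_ORDER}
    survivors: list[str] = []
    for ann in annotations:
        if ann.undefined or ann.maf < thresholds.maf_min:
            failed = "maf"
        elif tag_counts[ann.tag] > thresholds.max_snps_per_tag:
            failed = "snps_per_tag"
        elif ann.n_alleles not in (2, 3):
            failed = "n_alleles"
        elif not ann.call_rate > thresholds.call_rate_min:  # strict ">"
            failed = "call_rate"
        else:
            survivors.append(ann.locus)
            continue
        report.removed[failed] += 1
        report.removed_loci[failed].append(ann.locus)
    return G.restrict_loci(survivors), report
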