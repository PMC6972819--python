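"""Genotype matrices and their on-disk representations.

The central container is :class:`GenotypeMatrix`: an individuals x loci
integer dosage matrix (count of the alternate allele, 0/1/2) with a
dedicated missing sentinel and a population label per sample.  Three
dialects are supported: minimal diploid VCF (GT fields only, read via
cyvcf2), a GenAlEx-style codominant CSV with two allele columns per
locus, and a plain TSV dump used as the package's own round-trip format.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

#: Sentinel for a missing diploid call.  Never conflated with dosage 0.
MISSING: int = -1


class GenotypeIOError(ValueError):
    """Raised for malformed genotype input."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix for biallelic SNPs with population labels.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows).
    loci
        Ordered locus identifiers (columns).
    populations
        Mapping sample id -> population label; must cover every sample.
    calls
        ``(n_samples, n_loci)`` int8 array with entries in
        ``{0, 1, 2, MISSING}``.
    """

    samples: list[str]
    loci: list[str]
    populations: dict[str, str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise GenotypeIOError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeIOError("duplicate sample ids")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeIOError("duplicate locus ids")
        missing_labels = [s for s in self.samples if s not in self.populations]
        if missing_labels:
            raise GenotypeIOError(
                f"samples without population label: {missing_labels[:5]}"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeIOError("dosages must be 0, 1, 2 or MISSING")

    # -- basic queries -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_labels(self) -> list[str]:
        """Distinct population labels in first-seen sample order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s in self.samples if self.populations[s] == population]

    # -- derived matrices ----------------------------------------------

    def restrict_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        """Sub-matrix for the given samples, in the given order."""
        index = {s: i for i, s in enumerate(self.samples)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise GenotypeIOError(f"unknown sample id {exc.args[0]!r}") from exc
        return GenotypeMatrix(
            samples=list(sample_ids),
            loci=list(self.loci),
            populations={s: self.populations[s] for s in sample_ids},
            calls=self.calls[rows, :].copy(),
        )

    def restrict_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        """Sub-matrix for the given loci, in the given order."""
        index = {l: j for j, l in enumerate(self.loci)}
        try:
            cols = [index[l] for l in locus_ids]
        except KeyError as exc:
            raise GenotypeIOError(f"unknown locus id {exc.args[0]!r}") from exc
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=list(locus_ids),
            populations=dict(self.populations),
            calls=self.calls[:, cols].copy(),
        )

    def restrict_population(self, population: str) -> "GenotypeMatrix":
        return self.restrict_samples(self.samples_in(population))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and {s: self.populations[s] for s in self.samples}
            == {s: other.populations[s] for s in other.samples}
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------
# popmap


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sample_id<TAB>population`` map."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenotypeIOError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            popmap[parts[0]] = parts[1]
    return popmap


def write_popmap(popmap: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------
# VCF

_GT_CODE = {0: 0, 1: 1, 2: 2, 3: MISSING}  # cyvcf2 gts012 coding


def read_vcf(path: str | Path, popmap: Mapping[str, str] | str | Path) -> GenotypeMatrix:
    """Read a diploid VCF into a dosage matrix.

    Only biallelic SNP records are accepted; any multiallelic or
    non-SNP record aborts the read with the offending position named.
    ``0/0 -> 0``, ``0/1``/``1/0`` -> 1, ``1/1 -> 2``, ``./. -> MISSING``;
    phased separators are treated identically.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    popmap
        Either a mapping sample id -> population, or a path to a
        two-column TSV popmap.
    """
    if not isinstance(popmap, Mapping):
        popmap = read_popmap(popmap)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeIOError(f"{path}: VCF has no sample columns")
    loci: list[str] = []
    columns: list[np.ndarray] = []
    for record in vcf:
        site = f"{record.CHROM}:{record.POS}"
        if len(record.ALT) != 1:
            raise GenotypeIOError(
                f"{path}: multiallelic record at {site} (ALT={','.join(record.ALT)})"
            )
        if len(record.REF) != 1 or len(record.ALT[0]) != 1:
            raise GenotypeIOError(f"{path}: non-SNP record at {site}")
        if "GT" not in record.FORMAT:
            raise GenotypeIOError(f"{path}: record at {site} lacks a GT field")
        gts = record.gt_types
        columns.append(np.array([_GT_CODE[int(g)] for g in gts], dtype=np.int8))
        locus_id = record.ID if record.ID not in (None, ".") else site
        loci.append(locus_id)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=samples,
        loci=loci,
        populations={s: popmap[s] for s in samples},
        calls=calls,
    )


def write_vcf(G: GenotypeMatrix, path: str | Path, chrom: str = "1") -> None:
    """Write the matrix as a minimal single-contig VCF (GT only).

    Alleles are synthetic (REF=A, ALT=G); positions are 1-based column
    indices.  All statistics downstream are allele-label symmetric, so
    the synthetic alleles carry no information loss for dosage data.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={max(G.n_loci, 1) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, locus in enumerate(G.loci):
            gts = "\t".join(gt_str[int(d)] for d in G.calls[:, j])
            fh.write(f"{chrom}\t{j + 1}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------
# GenAlEx-style codominant CSV


def read_genalex_csv(
    path: str | Path, popmap: Mapping[str, str] | str | Path | None = None
) -> GenotypeMatrix:
    """Read a codominant two-columns-per-locus allele table.

    Layout: a header row ``sample,pop,<locus1>,,<locus2>,,...`` followed
    by one row per individual carrying two integer allele codes per
    locus.  ``0`` or blank marks a missing allele.  The reference allele
    at each locus is the lexicographically smaller code, so two equal
    codes map to dosage 0 or 2 and unequal codes to 1; all downstream
    statistics are allele-label symmetric, so this choice is neutral.

    If ``popmap`` is given it overrides the embedded ``pop`` column.
    """
    if popmap is not None and not isinstance(popmap, Mapping):
        popmap = read_popmap(popmap)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if any(cell.strip() for cell in row)]
    if not rows:
        raise GenotypeIOError(f"{path}: empty table")
    header = rows[0]
    if len(header) < 2:
        raise GenotypeIOError(f"{path}: header must start with sample,pop columns")
    locus_cells = header[2:]
    if len(locus_cells) % 2:
        raise GenotypeIOError(
            f"{path}: odd number of allele columns ({len(locus_cells)}); "
            "each locus needs exactly two"
        )
    loci = []
    for j in range(0, len(locus_cells), 2):
        name = locus_cells[j].strip()
        if not name:
            raise GenotypeIOError(f"{path}: blank locus name at column {j + 3}")
        loci.append(name)

    samples: list[str] = []
    populations: dict[str, str] = {}
    allele_rows: list[list[tuple[str, str]]] = []
    for lineno, row in enumerate(rows[1:], 2):
        if len(row) != len(header):
            raise GenotypeIOError(
                f"{path}:{lineno}: expected {len(header)} cells, got {len(row)}"
            )
        sample = row[0].strip()
        samples.append(sample)
        populations[sample] = row[1].strip()
        pairs = []
        for j in range(2, len(row), 2):
            a, b = row[j].strip(), row[j + 1].strip()
            pairs.append((a or "0", b or "0"))
        allele_rows.append(pairs)

    calls = np.full((len(samples), len(loci)), MISSING, dtype=np.int8)
    for j, locus in enumerate(loci):
        # reference allele = lexicographically smaller code; arbitrary but
        # fixed, and neutral because every statistic is label-symmetric
        codes = sorted({a for pairs in allele_rows for a in pairs[j] if a != "0"})
        if len(codes) > 2:
            raise GenotypeIOError(
                f"{path}: locus {locus!r} carries {len(codes)} allele codes "
                f"({', '.join(codes)}); at most 2 allowed"
            )
        ref = codes[0] if codes else None
        for i, pairs in enumerate(allele_rows):
            a, b = pairs[j]
            if a == "0" or b == "0":
                continue  # half-missing treated as missing call
            calls[i, j] = int(a != ref) + int(b != ref)

    if popmap is not None:
        populations = {s: popmap[s] for s in samples}
    return GenotypeMatrix(
        samples=samples, loci=loci, populations=populations, calls=calls
    )


def write_genalex_csv(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix in the codominant CSV dialect (alleles 1/2)."""
    pair = {0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2"), MISSING: ("0", "0")}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["sample", "pop"]
        for locus in G.loci:
            header.extend([locus, ""])
        writer.writerow(header)
        for i, sample in enumerate(G.samples):
            row = [sample, G.populations[sample]]
            for d in G.calls[i, :]:
                row.extend(pair[int(d)])
            writer.writerow(row)


# ---------------------------------------------------------------------
# TSV matrix dump (round-trip format)


def write_matrix(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: sample, population, one column per locus.

    Byte-stable for a fixed matrix; missing calls are written ``NA``.
    """
    with open(path, "w") as fh:
        header = "sample\tpopulation"
        if G.loci:
            header += "\t" + "\t".join(G.loci)
        fh.write(header + "\n")
        for i, sample in enumerate(G.samples):
            vals = "\t".join(
                "NA" if d == MISSING else str(int(d)) for d in G.calls[i, :]
            )
            line = f"{sample}\t{G.populations[sample]}"
            fh.write(line + ("\t" + vals if G.n_loci else "") + "\n")


def read_matrix(path: str | Path) -> GenotypeMatrix:
    """Read the TSV dump written by :func:`write_matrix`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample", "population"]:
            raise GenotypeIOError(f"{path}: not a genotype matrix dump")
        loci = header[2:]
        samples: list[str] = []
        populations: dict[str, str] = {}
        data: list[list[int]] = []
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise GenotypeIOError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            samples.append(parts[0])
            populations[parts[0]] = parts[1]
            data.append([MISSING if v == "NA" else int(v) for v in parts[2:]])
    calls = (
        np.array(data, dtype=np.int8)
        if data and loci
        else np.empty((len(samples), len(loci)), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=samples, loci=loci, populations=populations, calls=calls
    )
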