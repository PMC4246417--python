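"""Readers, writers and genomic indexing for the methylation pipeline.

File formats handled here are deliberately plain: BED-dialect tables of
per-CpG methylated/total read counts (one file per individual), 3+/4+ column
BED interval files for genomic annotations, GMT gene-set files and a
delimited sample sheet describing the sibling-pair design.

All interval logic is 0-based half-open ``[start, end)``. CpG positions are
the 0-based coordinate of the C on the + strand and counts are assumed
strand-collapsed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "CpGRecord",
    "MethylomeSample",
    "AnnotationSet",
    "GeneSetCollection",
    "Individual",
    "Cohort",
    "RegionIndex",
    "MethylationFormatError",
    "read_methylation_table",
    "write_methylation_table",
    "read_annotation_bed",
    "read_gene_sets",
    "read_sample_sheet",
    "filter_cpgs",
    "assign_cpgs_to_regions",
    "nearest_gene",
]

# (chromosome, 0-based position) uniquely keys a CpG across the cohort
CpGKey = tuple[str, int]

_RANDOM_CHROM = re.compile(r"random|un", re.IGNORECASE)


class MethylationFormatError(ValueError):
    """Raised when an input file violates the expected format or invariants."""


@dataclass(frozen=True)
class CpGRecord:
    chromosome: str
    position: int
    methylated_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise MethylationFormatError(
                f"total_reads must be positive at {self.chromosome}:{self.position}"
            )
        if not 0 <= self.methylated_reads <= self.total_reads:
            raise MethylationFormatError(
                f"methylated_reads ({self.methylated_reads}) exceeds total_reads "
                f"({self.total_reads}) at {self.chromosome}:{self.position}"
            )

    @property
    def key(self) -> CpGKey:
        return (self.chromosome, self.position)

    @property
    def fraction(self) -> float:
        return self.methylated_reads / self.total_reads


@dataclass
class MethylomeSample:
    """Per-CpG methylated/total read counts for one individual."""

    sample_id: str
    records: list[CpGRecord]

    def __post_init__(self) -> None:
        seen: set[CpGKey] = set()
        for rec in self.records:
            if rec.key in seen:
                raise MethylationFormatError(
                    f"duplicate CpG {rec.key} in sample {self.sample_id}"
                )
            seen.add(rec.key)

    def as_dict(self) -> dict[CpGKey, CpGRecord]:
        return {rec.key: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Region:
    chromosome: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise MethylationFormatError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )


@dataclass
class AnnotationSet:
    """A named collection of genomic intervals (one annotation class)."""

    name: str
    regions: list[Region]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(ids) != len(set(ids)):
            raise MethylationFormatError(
                f"duplicate region ids in annotation set {self.name}"
            )


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise MethylationFormatError(f"gene set {name} is empty")


@dataclass(frozen=True)
class Individual:
    sample_id: str
    pair_id: str
    exposed: bool
    sex: str
    age: float
    batch: str
    lmp_date: date | None = None
    phenotypes: Mapping[str, float | None] = field(default_factory=dict)


@dataclass
class Cohort:
    """Sibling-pair cohort: every pair has exactly one exposed member and
    both members share sex."""

    individuals: list[Individual]

    def __post_init__(self) -> None:
        by_pair: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            by_pair.setdefault(ind.pair_id, []).append(ind)
        for pid, members in by_pair.items():
            if len(members) != 2:
                raise MethylationFormatError(
                    f"pair {pid} has {len(members)} members, expected 2"
                )
            n_exposed = sum(m.exposed for m in members)
            if n_exposed != 1:
                raise MethylationFormatError(
                    f"pair {pid} has {n_exposed} exposed members, expected 1"
                )
            if members[0].sex != members[1].sex:
                raise MethylationFormatError(f"pair {pid} is sex-discordant")

    @property
    def pair_ids(self) -> list[str]:
        seen: list[str] = []
        for ind in self.individuals:
            if ind.pair_id not in seen:
                seen.append(ind.pair_id)
        return seen

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def pair(self, pair_id: str) -> tuple[Individual, Individual]:
        """Return (exposed, unexposed) members of a pair."""
        members = [i for i in self.individuals if i.pair_id == pair_id]
        exposed = next(m for m in members if m.exposed)
        control = next(m for m in members if not m.exposed)
        return exposed, control

    def exposure_vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {i.sample_id: i.exposed for i in self.individuals}
        return np.array([1.0 if lookup[s] else 0.0 for s in sample_ids])


@dataclass
class RegionIndex:
    """Maps region ids to their member CpGs and (optionally) nearest genes."""

    cpgs: dict[str, list[CpGKey]]
    nearest_genes: dict[str, str | None] = field(default_factory=dict)
    regions: dict[str, Region] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cpgs)


# ---------------------------------------------------------------------------
# readers / writers


def read_methylation_table(path: str | Path) -> MethylomeSample:
    """Read a BED-dialect per-CpG count table.

    Expected columns (tab-separated, no header): chromosome, start, end,
    methylated reads, total reads. A 4-column dialect without the ``end``
    column is also accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[CpGRecord] = []
    errors: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                errors.append(f"line {lineno}: expected >=4 columns, got {len(fields)}")
                continue
            if len(fields) >= 5:
                chrom, pos_s, _end, m_s, t_s = fields[:5]
            else:
                chrom, pos_s, m_s, t_s = fields[:4]
            try:
                pos, m, t = int(pos_s), int(m_s), int(t_s)
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinate or count")
                continue
            try:
                records.append(CpGRecord(chrom, pos, m, t))
            except MethylationFormatError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise MethylationFormatError(
            f"{path}: {len(errors)} malformed line(s): " + "; ".join(errors[:10])
        )
    return MethylomeSample(sample_id=path.stem, records=records)


def write_methylation_table(sample: MethylomeSample, path: str | Path) -> None:
    """Write a 5-column BED file, sorted lexicographically by chromosome and
    numerically by position, round-trippable by :func:`read_methylation_table`."""
    path = Path(path)
    ordered = sorted(sample.records, key=lambda r: (r.chromosome, r.position))
    with path.open("w") as fh:
        for rec in ordered:
            fh.write(
                f"{rec.chromosome}\t{rec.position}\t{rec.position + 2}\t"
                f"{rec.methylated_reads}\t{rec.total_reads}\n"
            )


def read_annotation_bed(path: str | Path, name: str) -> AnnotationSet:
    """Read a 3+ column BED into an :class:`AnnotationSet`; region ids come
    from column 4 when present, otherwise ``<name>_<n>``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    regions: list[Region] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line)
            if len(fields) < 3:
                raise MethylationFormatError(f"{path} line {lineno}: <3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MethylationFormatError(
                    f"{path} line {lineno}: unparseable coordinates"
                ) from exc
            region_id = fields[3] if len(fields) >= 4 else f"{name}_{len(regions)}"
            try:
                regions.append(Region(chrom, start, end, region_id))
            except MethylationFormatError as exc:
                raise MethylationFormatError(f"{path} line {lineno}: {exc}") from exc
    return AnnotationSet(name=name, regions=regions)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, members...); duplicate members
    within a set are collapsed, preserving first occurrence order."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MethylationFormatError(
                    f"{path} line {lineno}: GMT line needs >=3 fields"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if not deduped:
                raise MethylationFormatError(
                    f"{path} line {lineno}: gene set {name} has no members"
                )
            sets[name] = deduped
    return GeneSetCollection(sets=sets)


_REQUIRED_SHEET_COLUMNS = ("sample_id", "pair_id", "exposed", "sex", "age", "batch")


def read_sample_sheet(path: str | Path) -> Cohort:
    """Read a comma- or tab-separated sample sheet with a header.

    Required columns: sample_id, pair_id, exposed (0/1 or true/false), sex,
    age, batch. Optional: lmp_date (ISO format). Any other column becomes a
    phenotype; empty cells are missing.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        sniff = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if sniff.count("\t") >= sniff.count(",") else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise MethylationFormatError(f"{path}: empty sample sheet")
        missing = [c for c in _REQUIRED_SHEET_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise MethylationFormatError(f"{path}: missing columns {missing}")
        pheno_cols = [
            c
            for c in reader.fieldnames
            if c not in _REQUIRED_SHEET_COLUMNS and c != "lmp_date"
        ]
        individuals: list[Individual] = []
        for row in reader:
            lmp: date | None = None
            if row.get("lmp_date"):
                lmp = datetime.strptime(row["lmp_date"], "%Y-%m-%d").date()
            phenotypes = {
                c: (float(row[c]) if row.get(c) not in (None, "", "NA") else None)
                for c in pheno_cols
            }
            individuals.append(
                Individual(
                    sample_id=row["sample_id"],
                    pair_id=row["pair_id"],
                    exposed=str(row["exposed"]).strip().lower() in ("1", "true", "yes"),
                    sex=row["sex"],
                    age=float(row["age"]),
                    batch=row["batch"],
                    lmp_date=lmp,
                    phenotypes=phenotypes,
                )
            )
    return Cohort(individuals=individuals)


def write_sample_sheet(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    pheno_cols: list[str] = []
    for ind in cohort.individuals:
        for name in ind.phenotypes:
            if name not in pheno_cols:
                pheno_cols.append(name)
    header = list(_REQUIRED_SHEET_COLUMNS) + ["lmp_date"] + pheno_cols
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for ind in cohort.individuals:
            row = [
                ind.sample_id,
                ind.pair_id,
                int(ind.exposed),
                ind.sex,
                ind.age,
                ind.batch,
                ind.lmp_date.isoformat() if ind.lmp_date else "",
            ]
            for c in pheno_cols:
                v = ind.phenotypes.get(c)
                row.append("" if v is None else repr(float(v)))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# filtering and indexing


@dataclass
class CpGFilterReport:
    n_input: int
    n_kept: int
    n_low_coverage: int
    n_high_coverage: int
    n_random_chrom: int
    n_uninformative: int


def filter_cpgs(
    samples: Sequence[MethylomeSample],
    min_median_cov: float = 6,
    max_median_cov: float = 200,
) -> tuple[list[CpGKey], CpGFilterReport]:
    """Apply the cohort-level CpG inclusion rules.

    A CpG is kept iff (a) its median coverage across samples (absent
    observations count as 0) lies in ``[min_median_cov, max_median_cov]``,
    (b) its chromosome is not a random/unplaced contig and (c) its median
    methylation fraction across covering samples is strictly between 0 and 1.
    Exclusion counts are tallied per criterion in the order a, b, c (a CpG is
    counted once, at the first rule it fails).
    """
    if not samples:
        raise ValueError("at least one sample is required")
    all_keys: dict[CpGKey, None] = {}
    dicts = []
    for s in samples:
        d = s.as_dict()
        dicts.append(d)
        for k in d:
            all_keys.setdefault(k)
    kept: list[CpGKey] = []
    n_low = n_high = n_random = n_uninf = 0
    for key in all_keys:
        covs = np.array([d[key].total_reads if key in d else 0 for d in dicts])
        med_cov = float(np.median(covs))
        if med_cov < min_median_cov:
            n_low += 1
            continue
        if med_cov > max_median_cov:
            n_high += 1
            continue
        if _RANDOM_CHROM.search(key[0]):
            n_random += 1
            continue
        fracs = np.array([d[key].fraction for d in dicts if key in d])
        med_frac = float(np.median(fracs))
        if med_frac <= 0.0 or med_frac >= 1.0:
            n_uninf += 1
            continue
        kept.append(key)
    report = CpGFilterReport(
        n_input=len(all_keys),
        n_kept=len(kept),
        n_low_coverage=n_low,
        n_high_coverage=n_high,
        n_random_chrom=n_random,
        n_uninformative=n_uninf,
    )
    return kept, report


def assign_cpgs_to_regions(
    cpg_keys: Iterable[CpGKey], annotation: AnnotationSet
) -> RegionIndex:
    """Overlap-map CpGs to every containing region ([start, end) convention);
    regions with no covered CpG are dropped. Output is sorted by coordinate
    and independent of the input CpG ordering."""
    trees: dict[str, IntervalTree] = {}
    for region in annotation.regions:
        trees.setdefault(region.chromosome, IntervalTree()).addi(
            region.start, region.end, region
        )
    hits: dict[str, list[CpGKey]] = {}
    for key in cpg_keys:
        chrom, pos = key
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(pos):
            hits.setdefault(iv.data.region_id, []).append(key)
    cpgs = {rid: sorted(keys) for rid, keys in hits.items()}
    regions = {r.region_id: r for r in annotation.regions if r.region_id in cpgs}
    return RegionIndex(cpgs=cpgs, regions=regions)


def nearest_gene(
    region: Region,
    gene_intervals: Sequence[tuple[str, int, int, str]],
    max_dist: int = 100_000,
) -> str | None:
    """Nearest gene (by interval distance, 0 when overlapping) within
    ``max_dist``; ties broken by lexicographically smaller gene id."""
    best: tuple[int, str] | None = None
    for chrom, start, end, gene_id in gene_intervals:
        if chrom != region.chromosome:
            continue
        if end <= region.start:
            dist = region.start - end + 1
        elif region.end <= start:
            dist = start - region.end + 1
        else:
            dist = 0
        if dist > max_dist:
            continue
        cand = (dist, gene_id)
        if best is None or cand < best:
            best = cand
    return best[1] if best else None
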