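"""Data model and I/O for methylation haplotype blocks (MHBs).

An MHB is a short genomic interval whose CpG sites tend to be co-methylated
on single DNA molecules.  This module holds the on-disk dialects the rest of
the package consumes:

* ``regions.bed`` — BED4 (chrom, start, end, region_id), 0-based half-open;
* ``cpgs.tsv`` — two columns (chrom, pos), the forward-strand C of each CpG;
* ``<sample>.hap.tsv`` — six columns (chrom, start, end, pattern, count,
  strand) where ``start`` is the coordinate of the first CpG covered by the
  read and ``pattern`` is the read's methylation haplotype over consecutive
  CpGs ('1' methylated, '0' unmethylated);
* ``samples.tsv`` — sample metadata with header
  ``sample_id group cohort stage ca19_9 age sex`` (empty string = missing).

Reverse-strand reads are assumed pre-collapsed onto forward CpG units by the
upstream aligner; the strand column is carried but ignored by all metrics.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("PDAC", "CP", "Healthy")
COHORTS = ("train", "validation", "test", "discovery")
META_COLUMNS = ("sample_id", "group", "cohort", "stage", "ca19_9", "age", "sex")


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


@dataclass(frozen=True)
class RegionDef:
    """One methylation haplotype block: an interval plus its CpG ladder."""

    region_id: str
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.region_id}: empty interval")
        if len(self.cpg_positions) < 1:
            raise ValueError(f"region {self.region_id}: no CpGs")
        pos = self.cpg_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"region {self.region_id}: CpG positions not increasing")
        if pos[0] < self.start or pos[-1] >= self.end:
            raise ValueError(f"region {self.region_id}: CpGs outside [start,end)")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass(frozen=True)
class HaplotypeCount:
    """A read-level methylation pattern over consecutive CpGs of one region.

    ``first_cpg_index`` indexes into the region's ``cpg_positions``; the
    pattern covers that CpG and the following ``len(pattern) - 1`` CpGs.
    """

    region_id: str
    first_cpg_index: int
    pattern: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if len(self.pattern) < 1:
            raise ValueError("empty pattern")
        if set(self.pattern) - {"0", "1"}:
            raise ValueError(f"pattern {self.pattern!r} has characters outside {{0,1}}")
        if self.first_cpg_index < 0:
            raise ValueError("negative first_cpg_index")


@dataclass
class SampleHaplotypes:
    """All haplotype counts of one sample, keyed by region."""

    sample_id: str
    regions: dict[str, list[HaplotypeCount]] = field(default_factory=dict)

    def total_reads(self, region_id: str) -> int:
        return sum(h.count for h in self.regions.get(region_id, ()))


def read_cpgs(cpg_path: str | Path) -> pd.DataFrame:
    """Read the CpG coordinate table (chrom, pos); enforce per-chromosome order."""
    df = pd.read_csv(
        cpg_path, sep="\t", header=None, names=["chrom", "pos"],
        dtype={"chrom": str, "pos": np.int64}, comment="#",
    )
    if df.duplicated(["chrom", "pos"]).any():
        raise ParseError(f"{cpg_path}: duplicate CpG coordinates")
    for chrom, sub in df.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            # tolerate unsorted input but normalise; strict increase is checked above
            df.loc[sub.index, "pos"] = np.sort(sub["pos"].to_numpy())
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def read_regions(region_path: str | Path, cpg_path: str | Path) -> list[RegionDef]:
    """Load BED4 regions and attach the CpG positions falling inside each.

    Regions containing no CpG are an error (they could never carry a
    haplotype); duplicated region ids are an error.
    """
    cpgs = read_cpgs(cpg_path)
    by_chrom = {c: sub["pos"].to_numpy() for c, sub in cpgs.groupby("chrom", sort=False)}

    regions: list[RegionDef] = []
    seen: set[str] = set()
    with open(region_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{region_path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, region_id = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{region_path}:{lineno}: non-integer coordinate") from exc
            if region_id in seen:
                raise ParseError(f"{region_path}:{lineno}: duplicate region_id {region_id!r}")
            seen.add(region_id)
            pos = by_chrom.get(chrom, np.empty(0, dtype=np.int64))
            inside = pos[(pos >= start) & (pos < end)]
            if inside.size == 0:
                raise ParseError(
                    f"{region_path}:{lineno}: region {region_id!r} contains no CpGs"
                )
            regions.append(
                RegionDef(region_id, chrom, start, end, tuple(int(p) for p in inside))
            )
    return regions


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _cpg_lookup(regions: Sequence[RegionDef]) -> dict[tuple[str, int], tuple[str, int]]:
    """(chrom, cpg position) -> (region_id, index into the region's ladder)."""
    lut: dict[tuple[str, int], tuple[str, int]] = {}
    for reg in regions:
        for idx, pos in enumerate(reg.cpg_positions):
            lut[(reg.chrom, pos)] = (reg.region_id, idx)
    return lut


def read_haplotypes(
    hap_path: str | Path,
    regions: Sequence[RegionDef],
    sample_id: str | None = None,
) -> SampleHaplotypes:
    """Parse a 6-column haplotype TSV into per-region aggregated counts.

    Each record is anchored to a region by the coordinate of its first CpG.
    Reads running past the end of the region's CpG ladder are truncated to
    the in-region CpGs; reads anchored at no known CpG are skipped and the
    skip count logged.  Identical (region, offset, pattern) records are
    aggregated by summing counts.
    """
    by_id = {r.region_id: r for r in regions}
    lut = _cpg_lookup(regions)
    sample_id = sample_id or Path(hap_path).name.split(".")[0]
    agg: dict[tuple[str, int, str], int] = {}
    skipped = 0
    with _open_maybe_gzip(hap_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{hap_path}:{lineno}: expected 6 columns")
            chrom, start_s, _end, pattern, count_s, _strand = parts[:6]
            if set(pattern) - {"0", "1"}:
                raise ParseError(
                    f"{hap_path}:{lineno}: pattern {pattern!r} has characters outside {{0,1}}"
                )
            try:
                start, count = int(start_s), int(count_s)
            except ValueError as exc:
                raise ParseError(f"{hap_path}:{lineno}: non-integer field") from exc
            if count < 1:
                raise ParseError(f"{hap_path}:{lineno}: count must be >= 1")
            hit = lut.get((chrom, start))
            if hit is None:
                skipped += 1
                continue
            region_id, idx = hit
            region = by_id[region_id]
            room = region.n_cpgs - idx
            if len(pattern) > room:  # read spans the region boundary
                pattern = pattern[:room]
            key = (region_id, idx, pattern)
            agg[key] = agg.get(key, 0) + count
    if skipped:
        logger.info("%s: skipped %d records overlapping no region", hap_path, skipped)
    sample = SampleHaplotypes(sample_id)
    for (region_id, idx, pattern), count in sorted(agg.items()):
        sample.regions.setdefault(region_id, []).append(
            HaplotypeCount(region_id, idx, pattern, count)
        )
    return sample


def write_haplotypes(
    sample: SampleHaplotypes, regions: Sequence[RegionDef], path: str | Path
) -> None:
    """Write the 6-column haplotype TSV (inverse of :func:`read_haplotypes`)."""
    by_id = {r.region_id: r for r in regions}
    with open(path, "w") as fh:
        for region_id in sorted(sample.regions):
            reg = by_id[region_id]
            for hap in sorted(
                sample.regions[region_id], key=lambda h: (h.first_cpg_index, h.pattern)
            ):
                first = reg.cpg_positions[hap.first_cpg_index]
                last = reg.cpg_positions[hap.first_cpg_index + len(hap.pattern) - 1]
                fh.write(
                    f"{reg.chrom}\t{first}\t{last + 1}\t{hap.pattern}\t{hap.count}\t+\n"
                )


def write_regions(regions: Sequence[RegionDef], region_path: str | Path,
                  cpg_path: str | Path) -> None:
    with open(region_path, "w") as fh:
        for reg in regions:
            fh.write(f"{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.region_id}\n")
    with open(cpg_path, "w") as fh:
        for reg in sorted(regions, key=lambda r: (r.chrom, r.start)):
            for pos in reg.cpg_positions:
                fh.write(f"{reg.chrom}\t{pos}\n")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV; validates groups and CA19-9 sign."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=True)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id")
    bad = set(df["group"].dropna()) - set(GROUPS)
    if bad:
        raise ParseError(f"{path}: unknown group values {sorted(bad)}")
    ca = pd.to_numeric(df["ca19_9"], errors="coerce")
    if (ca.dropna() < 0).any():
        raise ParseError(f"{path}: negative CA19-9 value")
    df["ca19_9"] = ca
    return df.set_index("sample_id", drop=False)


def write_samples(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, columns=list(META_COLUMNS))


# ---------------------------------------------------------------------------
# MHB partitioning by co-methylation linkage


def _pair_r2(n11: int, n10: int, n01: int, n00: int) -> float | None:
    """Methylation-LD r^2 from the 2x2 joint counts of two CpG sites.

    Returns None when a margin is degenerate (one site constant) or no read
    covers both sites, which callers treat as a block boundary.
    """
    n = n11 + n10 + n01 + n00
    if n == 0:
        return None
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    denom = r1 * r0 * c1 * c0
    if denom == 0:
        return None
    num = n11 * n00 - n10 * n01
    return (num * num) / denom


def partition_mhbs(
    sample_set: Iterable[SampleHaplotypes],
    regions: Sequence[RegionDef],
    r2_min: float = 0.5,
    min_cpgs: int = 3,
) -> list[RegionDef]:
    """Split regions into blocks of tightly co-methylated consecutive CpGs.

    Reads are pooled over all samples; for every adjacent CpG pair the 2x2
    methylated/unmethylated joint counts (over reads covering both sites)
    give an LD-style r^2.  Maximal runs of >= ``min_cpgs`` CpGs in which
    every adjacent pair has r^2 >= ``r2_min`` become blocks.  Pairs with no
    co-covering reads are block boundaries.  Output ids are
    ``<region_id>.<k>`` with k counting blocks left to right.
    """
    blocks: list[RegionDef] = []
    for reg in regions:
        L = reg.n_cpgs
        if L < min_cpgs:
            continue
        joint = np.zeros((L - 1, 4), dtype=np.int64)  # columns: n11 n10 n01 n00
        for sample in sample_set:
            for hap in sample.regions.get(reg.region_id, ()):
                bits = np.frombuffer(hap.pattern.encode(), dtype=np.uint8) - ord("0")
                for k in range(len(bits) - 1):
                    j = hap.first_cpg_index + k
                    a, b = bits[k], bits[k + 1]
                    joint[j, (1 - a) * 2 + (1 - b)] += hap.count
        linked = np.zeros(L - 1, dtype=bool)
        for j in range(L - 1):
            r2 = _pair_r2(*joint[j])
            linked[j] = r2 is not None and r2 >= r2_min
        # maximal runs of linked adjacent pairs
        k, j = 0, 0
        while j < L - 1:
            if not linked[j]:
                j += 1
                continue
            j0 = j
            while j < L - 1 and linked[j]:
                j += 1
            n_sites = j - j0 + 1
            if n_sites >= min_cpgs:
                cpgs = reg.cpg_positions[j0 : j + 1]
                blocks.append(
                    RegionDef(f"{reg.region_id}.{k}", reg.chrom, cpgs[0], cpgs[-1] + 1, cpgs)
                )
                k += 1
    return blocks
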