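"""Block-level methylation haplotype measurements.

Seven measurements summarise the read-level methylation patterns of one
region in one sample:

* ``amf`` — average methylation fraction: methylated CpG observations over
  all CpG observations, pooled across reads.
* ``mhl`` / ``mhl3`` — methylation haplotype load: every read contributes
  all of its substrings of consecutive CpGs; for each length ``i`` the
  fraction ``P(MH_i)`` of fully methylated length-``i`` substrings is
  formed, and the load is the weighted mean ``sum(w_i * P(MH_i)) / sum(w_i)``
  with ``w_i = i`` (mhl) or ``w_i = i**3`` (mhl3), the sums running over the
  lengths for which any substring was observed.
* ``umhl`` / ``umhl3`` — the same loads computed for fully *un*methylated
  substrings.
* ``mhfm`` / ``mhfu`` — fraction of full-span reads (covering every CpG of
  the region) that are entirely methylated / entirely unmethylated.

All measurements live in [0, 1].  A measurement is missing only when its
denominator is empty (no reads; no full-span read for mhfm/mhfu) or when
the region's total read depth falls below the depth threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .store import HaplotypeCount, RegionDef, SampleHaplotypes

METRICS = ("amf", "mhl", "mhl3", "umhl", "umhl3", "mhfm", "mhfu")

DEFAULT_MIN_DEPTH = 10


@dataclass(frozen=True)
class RegionMetrics:
    """The seven measurements of one region in one sample (NaN = missing)."""

    region_id: str
    depth: int
    amf: float
    mhl: float
    mhl3: float
    umhl: float
    umhl3: float
    mhfm: float
    mhfu: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def _pattern_arrays(
    haps: Sequence[HaplotypeCount], n_cpgs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack haplotype records into (bits, counts) arrays.

    ``bits`` is (n_records, n_cpgs) int8 with -1 at CpGs the read does not
    cover.  Caller supplies records from one region only.
    """
    n = len(haps)
    bits = np.full((n, n_cpgs), -1, dtype=np.int8)
    counts = np.empty(n, dtype=np.float64)
    for row, hap in enumerate(haps):
        pat = np.frombuffer(hap.pattern.encode(), dtype=np.uint8) - ord("0")
        j = hap.first_cpg_index
        if j + pat.size > n_cpgs:
            raise ValueError(
                f"haplotype at offset {j} length {pat.size} exceeds region "
                f"ladder of {n_cpgs} CpGs"
            )
        bits[row, j : j + pat.size] = pat
        counts[row] = hap.count
    return bits, counts


def _grouped_metrics(
    bits: np.ndarray,
    counts: np.ndarray,
    sample_rows: np.ndarray,
    n_samples: int,
) -> dict[str, np.ndarray]:
    """Vectorised measurement computation for many samples of one region.

    ``sample_rows`` assigns each record row to a sample index.  Returns one
    length-``n_samples`` array per measurement plus ``depth``; missing values
    are NaN.  Substring counts are enumerated over all O(L^2) windows, which
    is cheap for the short CpG ladders MHBs have.
    """
    L = bits.shape[1]
    cov = bits >= 0
    meth = bits == 1
    unmeth = bits == 0

    def acc(weights: np.ndarray) -> np.ndarray:
        return np.bincount(sample_rows, weights=weights, minlength=n_samples)

    depth = acc(counts)
    amf_num = acc(counts * meth.sum(axis=1))
    amf_den = acc(counts * cov.sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        amf = np.where(amf_den > 0, amf_num / np.maximum(amf_den, 1), np.nan)
    amf[amf_den == 0] = np.nan

    # substring windows: tot[s, i-1] counts observed length-i windows etc.
    tot = np.zeros((n_samples, L))
    n_meth = np.zeros((n_samples, L))
    n_unmeth = np.zeros((n_samples, L))
    for i in range(1, L + 1):
        for j in range(0, L - i + 1):
            w_cov = cov[:, j : j + i].all(axis=1)
            if not w_cov.any():
                continue
            tot[:, i - 1] += acc(counts * w_cov)
            n_meth[:, i - 1] += acc(counts * (w_cov & meth[:, j : j + i].all(axis=1)))
            n_unmeth[:, i - 1] += acc(counts * (w_cov & unmeth[:, j : j + i].all(axis=1)))

    lengths = np.arange(1, L + 1, dtype=np.float64)
    observed = tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p_meth = np.where(observed, n_meth / np.maximum(tot, 1), 0.0)
        p_unmeth = np.where(observed, n_unmeth / np.maximum(tot, 1), 0.0)

    def load(p: np.ndarray, w: np.ndarray) -> np.ndarray:
        w_obs = observed * w
        den = w_obs.sum(axis=1)
        num = (p * w_obs).sum(axis=1)
        out = np.full(n_samples, np.nan)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out

    mhl = load(p_meth, lengths)
    mhl3 = load(p_meth, lengths**3)
    umhl = load(p_unmeth, lengths)
    umhl3 = load(p_unmeth, lengths**3)

    full = cov.all(axis=1)
    full_den = acc(counts * full)
    full_m = acc(counts * (full & meth.all(axis=1)))
    full_u = acc(counts * (full & unmeth.all(axis=1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        mhfm = np.where(full_den > 0, full_m / np.maximum(full_den, 1), np.nan)
        mhfu = np.where(full_den > 0, full_u / np.maximum(full_den, 1), np.nan)

    return {
        "depth": depth, "amf": amf, "mhl": mhl, "mhl3": mhl3,
        "umhl": umhl, "umhl3": umhl3, "mhfm": mhfm, "mhfu": mhfu,
    }


def region_metrics(haps: Sequence[HaplotypeCount], region: RegionDef) -> RegionMetrics:
    """Compute the seven measurements for one region of one sample.

    An empty haplotype list yields depth 0 and all-missing measurements; a
    region with no full-span read has mhfm/mhfu missing but the others
    defined.
    """
    if any(h.region_id != region.region_id for h in haps):
        raise ValueError("haplotypes do not all belong to the region")
    if len(haps) == 0:
        nan = float("nan")
        return RegionMetrics(region.region_id, 0, nan, nan, nan, nan, nan, nan, nan)
    bits, counts = _pattern_arrays(haps, region.n_cpgs)
    vals = _grouped_metrics(bits, counts, np.zeros(len(haps), dtype=np.intp), 1)
    return RegionMetrics(
        region.region_id,
        int(round(vals["depth"][0])),
        *(float(vals[m][0]) for m in METRICS),
    )


class MetricMatrix:
    """Samples x regions arrays, one per measurement, plus read depth.

    Entries are NaN where a region is missing in a sample — either because
    its read depth fell under ``min_depth`` or because the measurement's
    denominator was empty.  ``depth`` is always recorded.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        region_ids: Sequence[str],
        values: dict[str, np.ndarray],
        depth: np.ndarray,
        min_depth: int = DEFAULT_MIN_DEPTH,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.region_ids = list(region_ids)
        shape = (len(self.sample_ids), len(self.region_ids))
        for name in METRICS:
            if values[name].shape != shape:
                raise ValueError(f"metric {name!r} has shape {values[name].shape} != {shape}")
        self.values = {name: np.asarray(values[name], dtype=float) for name in METRICS}
        self.depth = np.asarray(depth, dtype=float)
        if self.depth.shape != shape:
            raise ValueError("depth shape mismatch")
        self.min_depth = int(min_depth)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.sample_ids), len(self.region_ids))

    def frame(self, metric: str) -> pd.DataFrame:
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}")
        return pd.DataFrame(self.values[metric], index=self.sample_ids,
                            columns=self.region_ids)

    def subset(self, sample_ids: Sequence[str] | None = None,
               region_ids: Sequence[str] | None = None) -> "MetricMatrix":
        sample_ids = self.sample_ids if sample_ids is None else list(sample_ids)
        region_ids = self.region_ids if region_ids is None else list(region_ids)
        rows = [self.sample_ids.index(s) for s in sample_ids]
        cols = [self.region_ids.index(r) for r in region_ids]
        values = {m: self.values[m][np.ix_(rows, cols)] for m in METRICS}
        return MetricMatrix(sample_ids, region_ids, values,
                            self.depth[np.ix_(rows, cols)], self.min_depth)

    def to_long(self) -> pd.DataFrame:
        """Long-format table: sample_id, region_id, metric, value, depth."""
        records = []
        for si, sid in enumerate(self.sample_ids):
            for ri, rid in enumerate(self.region_ids):
                d = self.depth[si, ri]
                for m in METRICS:
                    records.append((sid, rid, m, self.values[m][si, ri], d))
        return pd.DataFrame(records,
                            columns=["sample_id", "region_id", "metric", "value", "depth"])

    def to_tsv(self, path) -> None:
        df = self.to_long()
        df["value"] = df["value"].map(lambda v: "" if math.isnan(v) else f"{v:.10g}")
        df["depth"] = df["depth"].astype(int)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, min_depth: int = DEFAULT_MIN_DEPTH) -> "MetricMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "region_id": str})
        sample_ids = list(dict.fromkeys(df["sample_id"]))
        region_ids = list(dict.fromkeys(df["region_id"]))
        srow = {s: i for i, s in enumerate(sample_ids)}
        rcol = {r: i for i, r in enumerate(region_ids)}
        shape = (len(sample_ids), len(region_ids))
        values = {m: np.full(shape, np.nan) for m in METRICS}
        depth = np.zeros(shape)
        for row in df.itertuples(index=False):
            i, j = srow[row.sample_id], rcol[row.region_id]
            values[row.metric][i, j] = row.value
            depth[i, j] = row.depth
        return cls(sample_ids, region_ids, values, depth, min_depth)


def build_metric_matrix(
    cohort: Iterable[SampleHaplotypes],
    regions: Sequence[RegionDef],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> MetricMatrix:
    """Assemble the cohort measurement matrix with the depth missingness rule.

    A (sample, region) cell whose total read depth is below ``min_depth``
    has every measurement set to missing; the depth itself is kept.  The
    computation is grouped by region so each region's records across all
    samples are processed in one vectorised pass.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    cohort = list(cohort)
    sample_ids = [s.sample_id for s in cohort]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in cohort")
    region_ids = [r.region_id for r in regions]
    shape = (len(sample_ids), len(region_ids))
    values = {m: np.full(shape, np.nan) for m in METRICS}
    depth = np.zeros(shape)

    for ri, region in enumerate(regions):
        stacked: list[HaplotypeCount] = []
        rows: list[int] = []
        for si, sample in enumerate(cohort):
            haps = sample.regions.get(region.region_id, ())
            stacked.extend(haps)
            rows.extend([si] * len(haps))
        if not stacked:
            continue
        bits, counts = _pattern_arrays(stacked, region.n_cpgs)
        vals = _grouped_metrics(bits, counts, np.asarray(rows, dtype=np.intp),
                                len(sample_ids))
        depth[:, ri] = vals["depth"]
        shallow = vals["depth"] < min_depth
        for m in METRICS:
            col = vals[m]
            col[shallow] = np.nan
            values[m][:, ri] = col
    return MetricMatrix(sample_ids, region_ids, values, depth, min_depth)
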