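"""Differential-MHB marker discovery.

Discovery proceeds in stages mirroring a case–control marker screen:

1. region filtering — drop regions that are missing in too many samples or
   nearly constant;
2. differential selection — two-sided Wilcoxon rank-sum per region with
   Benjamini–Hochberg control, for tissue/tissue or tissue/plasma contrasts;
3. resampled plasma-vs-plasma selection — repeatedly balance cases against a
   random control subset, split into discovery/validation, select
   differential regions, and confirm them by a random forest's validation
   AUC, keeping regions that recur;
4. a literature/TSS window set and the final panel assembly by
   intersections and union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .metrics import METRICS, MetricMatrix
from .stats import mann_whitney_auc
from .store import RegionDef

logger = logging.getLogger(__name__)

DEFAULT_MAX_NA_RATE = 0.10
DEFAULT_MIN_VARIANCE = 0.02
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class FilterReport:
    regions_in: int
    removed_na_rate: int
    removed_low_variance: int
    regions_out: int


@dataclass
class MarkerRecord:
    region_id: str
    source: str  # T2T, T2P, P2P or literature; '+'-joined after assembly
    statistic: float = float("nan")
    p_value: float = float("nan")
    fdr_q: float = float("nan")
    selection_count: int | None = None


def filter_mhbs(
    matrix: MetricMatrix,
    metric: str = "amf",
    max_na_rate: float = DEFAULT_MAX_NA_RATE,
    min_variance: float = DEFAULT_MIN_VARIANCE,
) -> tuple[MetricMatrix, FilterReport]:
    """Drop regions with missing fraction > ``max_na_rate`` or sample
    variance < ``min_variance`` on the chosen measurement.

    Both inequalities are strict: a region at exactly the NA-rate threshold
    or exactly the variance threshold survives.  Variance is the unbiased
    sample variance of the non-missing values.
    """
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}")
    vals = matrix.values[metric]
    n_samples = vals.shape[0]
    na_rate = np.isnan(vals).sum(axis=0) / max(n_samples, 1)
    drop_na = na_rate > max_na_rate
    with np.errstate(invalid="ignore"):
        variance = np.array([
            np.nan if np.isnan(col).all() else np.nanvar(col, ddof=1)
            for col in vals.T
        ])
    drop_var = ~drop_na & ((variance < min_variance) | np.isnan(variance))
    keep = ~(drop_na | drop_var)
    kept_ids = [r for r, k in zip(matrix.region_ids, keep) if k]
    report = FilterReport(
        regions_in=len(matrix.region_ids),
        removed_na_rate=int(drop_na.sum()),
        removed_low_variance=int(drop_var.sum()),
        regions_out=len(kept_ids),
    )
    return matrix.subset(region_ids=kept_ids), report


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum.

    Exact null enumeration for small tie-free groups (both < 10), the
    tie-corrected normal approximation otherwise.
    """
    both = np.concatenate([x, y])
    ties = np.unique(both).size < both.size
    if x.size < 10 and y.size < 10 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def differential_mhbs(
    matrix: MetricMatrix,
    labels: pd.Series,
    metric: str = "amf",
    alpha: float = DEFAULT_ALPHA,
    source: str = "T2P",
    min_per_group: int = 3,
) -> list[MarkerRecord]:
    """Per-region Wilcoxon rank-sum with BH control across tested regions.

    ``labels`` maps sample_id to one of exactly two groups.  Regions with
    fewer than ``min_per_group`` non-missing values in either group are
    skipped (and logged).  Records with BH q < ``alpha`` are returned sorted
    by q then region_id.
    """
    labels = labels.reindex(matrix.sample_ids)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    mask_a = (labels == groups[0]).to_numpy()
    mask_b = (labels == groups[1]).to_numpy()
    vals = matrix.values[metric]
    tested: list[tuple[str, float, float]] = []
    skipped = 0
    for j, region_id in enumerate(matrix.region_ids):
        col = vals[:, j]
        a = col[mask_a & ~np.isnan(col)]
        b = col[mask_b & ~np.isnan(col)]
        if a.size < min_per_group or b.size < min_per_group:
            skipped += 1
            continue
        stat, p = _rank_sum_p(a, b)
        tested.append((region_id, stat, p))
    if skipped:
        logger.info("differential_mhbs: skipped %d regions with sparse groups", skipped)
    if not tested:
        return []
    pvals = np.array([t[2] for t in tested])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    records = [
        MarkerRecord(rid, source, stat, p, float(q))
        for (rid, stat, p), q in zip(tested, qvals)
        if q < alpha
    ]
    records.sort(key=lambda r: (r.fdr_q, r.region_id))
    return records


def _vectorised_rank_sum(vals: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
                         min_per_group: int) -> np.ndarray:
    """Column-wise asymptotic Wilcoxon p-values (NaN where groups sparse).

    Used inside the resampling loop where thousands of tests are run; the
    asymptotic tie-corrected approximation is applied throughout for speed.
    """
    a = vals[mask_a]
    b = vals[mask_b]
    n_a = (~np.isnan(a)).sum(axis=0)
    n_b = (~np.isnan(b)).sum(axis=0)
    ok = (n_a >= min_per_group) & (n_b >= min_per_group)
    p = np.full(vals.shape[1], np.nan)
    if ok.any():
        with np.errstate(invalid="ignore"):
            res = sps.mannwhitneyu(
                a[:, ok], b[:, ok], alternative="two-sided",
                method="asymptotic", nan_policy="omit", axis=0,
            )
        p[ok] = np.atleast_1d(res.pvalue)
    return p


def p2p_selection(
    matrix: MetricMatrix,
    cases: Sequence[str],
    controls: Sequence[str],
    metric: str = "amf",
    iters: int = 500,
    n_balance: int = 20,
    split: tuple[int, int, int, int] = (15, 15, 5, 5),
    alpha: float = DEFAULT_ALPHA,
    auc_min: float = 0.75,
    count_min: int = 300,
    seed: int | None = None,
    n_trees: int = 500,
) -> list[MarkerRecord]:
    """Resampled case/control marker selection with random-forest validation.

    Each iteration draws ``n_balance`` controls without replacement, splits
    cases and the drawn controls into a discovery set and a validation set
    per ``split`` (discovery cases, discovery controls, validation cases,
    validation controls), selects differential regions in the discovery set
    (Wilcoxon, BH q < ``alpha``), trains a random forest on them, and — only
    if the validation AUC reaches ``auc_min`` — credits each selected region
    with one selection.  Regions selected strictly more than ``count_min``
    times are returned.  Fully deterministic given ``seed``.
    """
    d_cases, d_ctrl, v_cases, v_ctrl = split
    if len(cases) < d_cases + v_cases:
        raise ValueError("too few cases for the requested split")
    if len(controls) < n_balance or n_balance < d_ctrl + v_ctrl:
        raise ValueError("too few controls for the requested balance/split")
    rng = np.random.default_rng(seed)
    cases = list(cases)
    controls = list(controls)
    srow = {s: i for i, s in enumerate(matrix.sample_ids)}
    vals = matrix.values[metric]
    counts: dict[str, int] = {}
    failed = 0
    region_arr = np.asarray(matrix.region_ids)

    for _ in range(iters):
        picked_ctrl = [controls[i] for i in rng.choice(len(controls), n_balance, replace=False)]
        case_perm = [cases[i] for i in rng.permutation(len(cases))]
        ctrl_perm = [picked_ctrl[i] for i in rng.permutation(n_balance)]
        disc = case_perm[:d_cases] + ctrl_perm[:d_ctrl]
        disc_y = np.array([1] * d_cases + [0] * d_ctrl)
        val = case_perm[d_cases:d_cases + v_cases] + ctrl_perm[d_ctrl:d_ctrl + v_ctrl]
        val_y = np.array([1] * v_cases + [0] * v_ctrl)

        disc_rows = np.array([srow[s] for s in disc])
        sub = vals[disc_rows]
        p = _vectorised_rank_sum(sub, disc_y == 1, disc_y == 0, min_per_group=3)
        tested = ~np.isnan(p)
        if not tested.any():
            failed += 1
            continue
        _, q, _, _ = multipletests(p[tested], method="fdr_bh")
        hits = region_arr[tested][q < alpha]
        if hits.size == 0:
            failed += 1
            continue

        cols = [srow_region for srow_region in (np.flatnonzero(region_arr == h)[0] for h in hits)]
        x_disc = vals[np.ix_(disc_rows, cols)]
        x_val = vals[np.ix_(np.array([srow[s] for s in val]), cols)]
        # random forests need finite inputs; fill residual missingness with
        # the discovery-set column means
        col_mean = np.nanmean(x_disc, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)
        x_disc = np.where(np.isnan(x_disc), col_mean, x_disc)
        x_val = np.where(np.isnan(x_val), col_mean, x_val)
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        forest.fit(x_disc, disc_y)
        scores = forest.predict_proba(x_val)[:, 1]
        if mann_whitney_auc(scores, val_y) >= auc_min:
            for h in hits:
                counts[h] = counts.get(h, 0) + 1
    if failed:
        logger.info("p2p_selection: %d/%d iterations yielded no differential markers",
                    failed, iters)
    records = [
        MarkerRecord(rid, "P2P", selection_count=c)
        for rid, c in counts.items() if c > count_min
    ]
    records.sort(key=lambda r: r.region_id)
    return records


def tss_markers(
    regions: Sequence[RegionDef],
    tss_bed: str | Path,
    gene_list: str | Path,
    window: tuple[int, int] = (1500, 1000),
) -> list[MarkerRecord]:
    """Regions overlapping the strand-aware promoter window of listed genes.

    The window spans ``window[0]`` bp upstream to ``window[1]`` bp downstream
    of each gene's transcription start site; for '-'-strand genes upstream
    means higher coordinates.  Genes named in ``gene_list`` but absent from
    the TSS BED are logged and skipped.
    """
    upstream, downstream = window
    with open(gene_list) as fh:
        wanted = {line.strip() for line in fh if line.strip()}
    tss: dict[str, tuple[str, int, str]] = {}
    with open(tss_bed) as fh:
        for raw in fh:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 6 or raw.startswith(("#", "track")):
                continue
            chrom, start, _end, gene, _score, strand = parts[:6]
            tss[gene] = (chrom, int(start), strand)
    absent = wanted - set(tss)
    if absent:
        logger.info("tss_markers: %d listed genes absent from TSS bed", len(absent))
    windows: list[tuple[str, int, int]] = []
    for gene in sorted(wanted & set(tss)):
        chrom, pos, strand = tss[gene]
        if strand == "-":
            lo, hi = pos - downstream, pos + upstream
        else:
            lo, hi = pos - upstream, pos + downstream
        windows.append((chrom, lo, hi))
    hits: list[MarkerRecord] = []
    for reg in regions:
        for chrom, lo, hi in windows:
            if reg.chrom == chrom and reg.start <= hi and reg.end - 1 >= lo:
                hits.append(MarkerRecord(reg.region_id, "literature"))
                break
    return hits


def assemble_panel(
    t2t: Sequence[MarkerRecord],
    t2p: Sequence[MarkerRecord],
    p2p: Sequence[MarkerRecord],
    literature: Sequence[MarkerRecord],
) -> list[MarkerRecord]:
    """Panel = (T2T ∩ T2P) ∪ (T2T ∩ literature) ∪ P2P, deduplicated.

    Each surviving record carries the '+'-joined sorted set of every source
    it appeared in; ordering is stable by region_id.
    """
    by_region: dict[str, set[str]] = {}
    stats: dict[str, MarkerRecord] = {}
    for rec_list in (t2t, t2p, p2p, literature):
        for rec in rec_list:
            by_region.setdefault(rec.region_id, set()).add(rec.source)
            stats.setdefault(rec.region_id, rec)
    t2t_ids = {r.region_id for r in t2t}
    t2p_ids = {r.region_id for r in t2p}
    lit_ids = {r.region_id for r in literature}
    p2p_ids = {r.region_id for r in p2p}
    chosen = (t2t_ids & t2p_ids) | (t2t_ids & lit_ids) | p2p_ids
    panel = []
    for rid in sorted(chosen):
        proto = stats[rid]
        panel.append(MarkerRecord(
            rid, "+".join(sorted(by_region[rid])),
            proto.statistic, proto.p_value, proto.fdr_q, proto.selection_count,
        ))
    return panel


def markers_to_frame(records: Sequence[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.region_id, r.source, r.statistic, r.p_value, r.fdr_q,
          "" if r.selection_count is None else r.selection_count)
         for r in records],
        columns=["region_id", "source", "stat", "p", "q", "selection_count"],
    )
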