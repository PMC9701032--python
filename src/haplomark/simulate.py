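"""Synthetic tissue/plasma cohort generator.

The generator emulates the statistical structure the pipeline assumes while
staying fully in memory and deterministic:

* each region has a background methylation mode drawn from a bimodal
  (mostly-unmethylated / mostly-methylated) mixture, with per-sample latent
  levels Beta-distributed around the mode;
* at designated true-marker regions, case samples carry a minority read
  population at a shifted "tumour" level — a read-level mixture mirroring
  ctDNA dilution at tumour fraction f, so the expected case-control AMF
  shift is f*delta;
* within a read, with probability rho all CpGs share one Bernoulli draw
  (co-methylation), otherwise CpGs are independent — this is what makes
  haplotype loads genuinely different from the mean methylation level;
* read counts per region are negative-binomial, reads cover contiguous CpG
  windows, and whole regions drop out at a small missingness rate;
* CA19-9 is lognormal by group with a fixed fraction of cases forced below
  the 37 U/ml clinical negativity threshold (Lewis-negative mimics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .store import META_COLUMNS, HaplotypeCount, RegionDef, SampleHaplotypes

CA19_9_NEGATIVE_THRESHOLD = 37.0  # U/ml


@dataclass(frozen=True)
class CohortDesign:
    """Full parameterization of one synthetic cohort."""

    n_regions: int = 200
    n_true_markers: int = 20
    # split name -> (n cases, n controls)
    splits: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"train": (60, 60), "validation": (30, 30)})
    # background methylation mixture
    mu_low: float = 0.15
    mu_high: float = 0.85
    p_high: float = 0.5
    kappa: float = 15.0
    # tumour signal
    delta: float = 0.4
    tumour_fraction: float = 0.2
    # read model
    rho: float = 0.7
    coverage_mean: float = 50.0
    coverage_dispersion: float = 10.0
    span_p: float = 0.85          # per-extra-CpG retention; span = 1 + Binom(L-1, span_p)
    cpg_count_range: tuple[int, int] = (3, 8)
    missing_region_rate: float = 0.02
    # CA19-9 (U/ml): lognormal medians and ln-scale sigmas per group
    ca_control_median: float = 4.0
    ca_control_sigma: float = 0.8
    ca_case_median: float = 421.6
    ca_case_sigma: float = 1.5
    ca_cp_median: float = 109.6
    ca_cp_sigma: float = 1.2
    lewis_negative_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_high", "rho", "tumour_fraction", "missing_region_rate",
                     "lewis_negative_fraction", "span_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_true_markers > self.n_regions:
            raise ValueError("n_true_markers exceeds n_regions")


@dataclass
class CohortTruth:
    """What was planted: marker truth per region, tumour fraction per sample."""

    regions: pd.DataFrame   # region_id, is_true_marker, direction, background_mu
    samples: pd.DataFrame   # sample_id, tumour_fraction

    def true_marker_ids(self) -> set[str]:
        sub = self.regions[self.regions["is_true_marker"]]
        return set(sub["region_id"])


def simulate_regions(design: CohortDesign, seed: int | None = None
                     ) -> tuple[list[RegionDef], pd.DataFrame]:
    """Place non-overlapping regions on a synthetic chromosome.

    CpG counts are uniform over ``cpg_count_range``; intra-region CpG
    spacing 10-29 bp, inter-region gap 500 bp.  Returns the regions and the
    flat CpG coordinate table.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lo, hi = design.cpg_count_range
    regions: list[RegionDef] = []
    cursor = 1000
    rows = []
    for i in range(design.n_regions):
        n_cpg = int(rng.integers(lo, hi + 1))
        gaps = rng.integers(10, 30, size=n_cpg - 1) if n_cpg > 1 else np.empty(0, int)
        positions = cursor + np.concatenate([[0], np.cumsum(gaps)]).astype(int)
        start = int(positions[0] - 2)
        end = int(positions[-1] + 3)
        region_id = f"r{i:04d}"
        regions.append(RegionDef(region_id, "chrS", start, end,
                                 tuple(int(p) for p in positions)))
        rows.extend(("chrS", int(p)) for p in positions)
        cursor = end + 500
    cpgs = pd.DataFrame(rows, columns=["chrom", "pos"])
    return regions, cpgs


def _encode_reads(bits: np.ndarray, starts: np.ndarray, spans: np.ndarray,
                  sample_rows: np.ndarray, region_id: str,
                  per_sample: list[SampleHaplotypes]) -> None:
    """Aggregate raw per-read patterns into HaplotypeCount records."""
    L = bits.shape[1]
    cols = np.arange(L)
    rel = cols[None, :] - starts[:, None]
    covered = (rel >= 0) & (rel < spans[:, None])
    vals = np.where(covered & (bits == 1), 1 << np.clip(rel, 0, 62), 0).sum(axis=1)
    keys = np.stack([sample_rows, starts, spans, vals], axis=1)
    uniq, counts = np.unique(keys, axis=0, return_counts=True)
    for (srow, start, span, val), count in zip(uniq, counts):
        pattern = "".join("1" if (val >> k) & 1 else "0" for k in range(span))
        per_sample[srow].regions.setdefault(region_id, []).append(
            HaplotypeCount(region_id, int(start), pattern, int(count)))


def simulate_cohort(
    design: CohortDesign,
    regions: Sequence[RegionDef],
    seed: int | None = None,
) -> tuple[list[SampleHaplotypes], pd.DataFrame, CohortTruth]:
    """Draw read-level haplotypes, sample metadata and the planted truth."""
    rng = np.random.default_rng(design.seed if seed is None else seed)

    sample_ids: list[str] = []
    groups: list[str] = []
    cohorts: list[str] = []
    for split, (n_cases, n_controls) in design.splits.items():
        for i in range(n_cases):
            sample_ids.append(f"{split}_case_{i:03d}")
            groups.append("PDAC")
            cohorts.append(split)
        for i in range(n_controls):
            sample_ids.append(f"{split}_ctrl_{i:03d}")
            groups.append("Healthy")
            cohorts.append(split)
    n_samples = len(sample_ids)
    is_case = np.array([g == "PDAC" for g in groups])

    # planted truth
    true_idx = rng.choice(design.n_regions, size=design.n_true_markers, replace=False)
    is_true = np.zeros(design.n_regions, dtype=bool)
    is_true[true_idx] = True
    mu_region = np.where(rng.random(design.n_regions) < design.p_high,
                         design.mu_high, design.mu_low)
    direction = np.where(mu_region <= 0.5, 1, -1)  # shift away from the mode
    tumour_level = np.clip(mu_region + direction * design.delta, 0.02, 0.98)
    f_sample = np.where(is_case, design.tumour_fraction, 0.0)

    per_sample = [SampleHaplotypes(sid) for sid in sample_ids]
    disp = design.coverage_dispersion
    nb_p = disp / (disp + design.coverage_mean)

    for ri, region in enumerate(regions):
        L = region.n_cpgs
        n_reads = rng.negative_binomial(disp, nb_p, size=n_samples)
        silenced = rng.random(n_samples) < design.missing_region_rate
        n_reads[silenced] = 0
        R = int(n_reads.sum())
        if R == 0:
            continue
        sample_rows = np.repeat(np.arange(n_samples), n_reads)

        a, b = mu_region[ri] * design.kappa, (1 - mu_region[ri]) * design.kappa
        theta_bg = rng.beta(a, b, size=n_samples)
        if is_true[ri]:
            t = tumour_level[ri]
            theta_tum = rng.beta(t * design.kappa, (1 - t) * design.kappa,
                                 size=n_samples)
            tumour_read = rng.random(R) < f_sample[sample_rows]
            theta_read = np.where(tumour_read, theta_tum[sample_rows],
                                  theta_bg[sample_rows])
        else:
            theta_read = theta_bg[sample_rows]

        spans = 1 + rng.binomial(L - 1, design.span_p, size=R) if L > 1 \
            else np.ones(R, dtype=int)
        starts = rng.integers(0, L - spans + 1)
        correlated = rng.random(R) < design.rho
        shared = (rng.random(R) < theta_read).astype(np.int8)
        indep = (rng.random((R, L)) < theta_read[:, None]).astype(np.int8)
        bits = np.where(correlated[:, None], shared[:, None], indep)
        cols = np.arange(L)
        covered = (cols[None, :] >= starts[:, None]) & \
                  (cols[None, :] < (starts + spans)[:, None])
        bits = np.where(covered, bits, np.int8(-1))
        _encode_reads(bits, starts, spans, sample_rows, region.region_id, per_sample)

    ca_values = simulate_ca199(design, groups, seed=int(rng.integers(0, 2**31 - 1)))

    stage_pool = np.array(["I", "IIA", "IIB", "III", "IV"])
    stage_probs = np.array([0.19, 0.27, 0.26, 0.17, 0.11])
    stages = np.where(
        is_case, rng.choice(stage_pool, size=n_samples, p=stage_probs), "")
    ages = np.clip(np.round(rng.normal(60, 9, size=n_samples)), 25, 88).astype(int)
    sexes = rng.choice(["M", "F"], size=n_samples)
    meta = pd.DataFrame({
        "sample_id": sample_ids, "group": groups, "cohort": cohorts,
        "stage": stages, "ca19_9": np.round(ca_values, 1),
        "age": ages, "sex": sexes,
    }, columns=list(META_COLUMNS)).set_index("sample_id", drop=False)

    truth = CohortTruth(
        regions=pd.DataFrame({
            "region_id": [r.region_id for r in regions],
            "is_true_marker": is_true,
            "direction": direction * is_true,
            "background_mu": mu_region,
        }),
        samples=pd.DataFrame({"sample_id": sample_ids,
                              "tumour_fraction": f_sample}),
    )
    return per_sample, meta, truth


def simulate_ca199(design: CohortDesign, groups: Sequence[str],
                   seed: int | None = None) -> np.ndarray:
    """Group-wise lognormal CA19-9 with a forced Lewis-negative case fraction.

    Exactly ``ceil(lewis_negative_fraction * n_cases)`` randomly chosen cases
    are redrawn from the case lognormal truncated below 37 U/ml.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    groups = np.asarray(groups)
    params = {
        "Healthy": (np.log(design.ca_control_median), design.ca_control_sigma),
        "PDAC": (np.log(design.ca_case_median), design.ca_case_sigma),
        "CP": (np.log(design.ca_cp_median), design.ca_cp_sigma),
    }
    values = np.empty(groups.size)
    for group, (mu, sigma) in params.items():
        mask = groups == group
        values[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
    case_idx = np.flatnonzero(groups == "PDAC")
    n_neg = int(np.ceil(design.lewis_negative_fraction * case_idx.size))
    if n_neg > 0:
        mu, sigma = params["PDAC"]
        chosen = rng.choice(case_idx, size=n_neg, replace=False)
        # inverse-CDF draw from the truncated-below-37 lognormal
        cap = sps.norm.cdf((np.log(CA19_9_NEGATIVE_THRESHOLD) - mu) / sigma)
        u = rng.random(n_neg) * cap
        values[chosen] = np.exp(mu + sigma * sps.norm.ppf(u))
    return values


def null_design(design: CohortDesign | None = None) -> CohortDesign:
    """A copy of ``design`` with the tumour signal removed (f = 0)."""
    base = design or CohortDesign()
    return replace(base, tumour_fraction=0.0)
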