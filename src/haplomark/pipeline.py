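"""End-to-end orchestration: simulate → metrics → discover → train → predict → evaluate.

The pipeline is a library function (:func:`run_pipeline`) that the CLI wraps.
All stage outputs are plain TSV/JSON so runs are diff-able; given the same
config and seed a re-run is byte-identical.  Labels of held-out splits are
consumed only in the evaluation stage — prediction sees features only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify, discovery, metrics as metrics_mod, simulate, stats, store

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every threshold of the pipeline, with its conventional default."""

    min_depth: int = 10
    max_na_rate: float = 0.10
    min_variance: float = 0.02
    # The variance screen targets undiluted tissue contrasts; plasma signals
    # are ctDNA-diluted (shift ~ f*delta), so by default the plasma pipeline
    # applies only the NA-rate filter and leaves the variance screen off.
    apply_variance_filter: bool = False
    alpha: float = 0.05
    discovery_metric: str = "amf"
    min_detection: float = 0.90
    p2p_iters: int = 500
    p2p_auc_min: float = 0.75
    p2p_count_min: int = 300
    p2p_n_balance: int = 20
    use_p2p: bool = False
    folds: int = 10
    knn_k: int = 5
    bootstrap_reps: int = 1000
    cutoff_mode: str = "youden"
    fixed_specificity: float = 0.89
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    fallback_top_markers: int = 10
    seed: int = 0
    design: simulate.CohortDesign = field(default_factory=simulate.CohortDesign)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design_raw = raw.pop("design", {})
        if "splits" in design_raw:
            design_raw["splits"] = {k: tuple(v) for k, v in design_raw["splits"].items()}
        if "cpg_count_range" in design_raw:
            design_raw["cpg_count_range"] = tuple(design_raw["cpg_count_range"])
        return cls(design=simulate.CohortDesign(**design_raw), **raw)

    def effective_values(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["splits"] = {k: list(v) for k, v in self.design.splits.items()}
        d["design"]["cpg_count_range"] = list(self.design.cpg_count_range)
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    regions: list[store.RegionDef]
    cohort: list[store.SampleHaplotypes]
    meta: pd.DataFrame
    truth: simulate.CohortTruth
    matrix: metrics_mod.MetricMatrix
    filter_report: discovery.FilterReport
    markers: list[discovery.MarkerRecord]
    measurements: list[classify.RegionalMeasurement]
    classifier: classify.TrainedClassifier
    predictions: pd.DataFrame
    report: pd.DataFrame
    combined_model: classify.CombinatorialModel | None = None

    def selected_region_ids(self) -> list[str]:
        return [m.split(":")[0] for m in self.classifier.markers]


def _derive_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _split_ids(meta: pd.DataFrame, cohort_name: str) -> list[str]:
    return list(meta.loc[meta["cohort"] == cohort_name, "sample_id"])


def discover_markers(
    matrix: metrics_mod.MetricMatrix,
    labels: pd.Series,
    config: RunConfig,
) -> tuple[metrics_mod.MetricMatrix, discovery.FilterReport, list[discovery.MarkerRecord]]:
    """Filter + differential selection, with a ranked fallback.

    When no region clears the FDR threshold (a null cohort, say), the
    ``fallback_top_markers`` smallest-p regions are passed on so a model can
    still be trained and honestly evaluated downstream.
    """
    min_var = config.min_variance if config.apply_variance_filter else 0.0
    filtered, report = discovery.filter_mhbs(
        matrix, config.discovery_metric, config.max_na_rate, min_var)
    all_recs = discovery.differential_mhbs(
        filtered, labels, config.discovery_metric, alpha=2.0)
    selected = [r for r in all_recs if r.fdr_q < config.alpha]
    if not selected:
        logger.info("no differential regions at q<%.3g; falling back to top %d by p",
                    config.alpha, config.fallback_top_markers)
        selected = sorted(all_recs, key=lambda r: (r.p_value, r.region_id))
        selected = selected[: config.fallback_top_markers]
    return filtered, report, selected


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on a synthetic cohort defined by ``config.design``.

    The classifier is built on the 'train' split only; every other split is
    scored blind and labels enter only at evaluation.
    """
    seeds = _derive_seeds(config.seed, 5)
    design = config.design

    regions, _cpgs = simulate.simulate_regions(design, seed=seeds[0])
    cohort, meta, truth = simulate.simulate_cohort(design, regions, seed=seeds[1])
    matrix = metrics_mod.build_metric_matrix(cohort, regions, config.min_depth)

    train_ids = _split_ids(meta, "train")
    if not train_ids:
        raise RuntimeError("stage train: design has no 'train' split")
    labels_all = meta["group"]
    y_train = (labels_all.loc[train_ids] == "PDAC").astype(int).to_numpy()

    train_matrix = matrix.subset(sample_ids=train_ids)
    filtered, filter_report, marker_recs = discover_markers(
        train_matrix, labels_all.loc[train_ids], config)

    detected = set(classify.detected_markers(
        train_matrix, config.min_detection, config.discovery_metric))
    candidates = [r.region_id for r in marker_recs if r.region_id in detected]
    if not candidates:
        raise RuntimeError("stage discover: no detected candidate markers")

    measurements = [
        classify.select_measurement(train_matrix, labels_all.loc[train_ids], m)
        for m in candidates
    ]
    measurements.sort(key=lambda m: (m.wald_p, m.region_id))

    feats_train = classify.feature_table(train_matrix, measurements)
    prep = classify.fit_preprocessor(feats_train, config.knn_k)
    train_proc = prep.apply(feats_train)
    ranked = [c for c in (f"{m.region_id}:{m.metric}" for m in measurements)
              if c in prep.columns]
    if not ranked:
        raise RuntimeError("stage train: every candidate dropped by preprocessing")

    selected, trace = classify.incremental_select(
        train_proc, y_train, ranked, folds=config.folds, seed=seeds[2],
        kernel=config.svm_kernel, C=config.svm_C)
    clf = classify.train_classifier(
        train_proc, y_train, selected, prep, seed=seeds[2],
        kernel=config.svm_kernel, C=config.svm_C, cv_trace=trace,
        cutoff_mode=config.cutoff_mode, fixed_specificity=config.fixed_specificity)

    # prediction: features only, for every sample
    sel_meas = [m for m in measurements if f"{m.region_id}:{m.metric}" in prep.columns]
    feats_all = classify.feature_table(matrix, sel_meas)
    scores = clf.score(feats_all)
    predictions = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "cohort": meta.loc[matrix.sample_ids, "cohort"].to_numpy(),
        "score": np.round(scores, 10),
        "call": (scores >= clf.cutoff).astype(int),
    })

    # optional CA19-9 integration on training samples with CA19-9 values
    combined_model = None
    train_meta = meta.loc[train_ids]
    ca_ok = train_meta["ca19_9"].notna()
    if ca_ok.sum() >= 10:
        train_scores = predictions.set_index("sample_id").loc[train_ids, "score"]
        combined_model, _ = classify.combine_ca199(
            train_scores[ca_ok.to_numpy()].to_numpy(),
            train_meta.loc[ca_ok, "ca19_9"].to_numpy(),
            y_train[ca_ok.to_numpy()])

    report = evaluate_predictions(predictions, meta, clf.cutoff,
                                  reps=config.bootstrap_reps, seed=seeds[3],
                                  combined_model=combined_model)

    result = PipelineResult(
        config=config, regions=regions, cohort=cohort, meta=meta, truth=truth,
        matrix=matrix, filter_report=filter_report, markers=marker_recs,
        measurements=measurements, classifier=clf,
        predictions=predictions, report=report, combined_model=combined_model)
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


def evaluate_predictions(
    predictions: pd.DataFrame,
    meta: pd.DataFrame,
    cutoff: float,
    reps: int = 1000,
    seed: int | None = None,
    combined_model: classify.CombinatorialModel | None = None,
) -> pd.DataFrame:
    """Per-split AUC with bootstrap CI plus Clopper–Pearson sensitivity and
    specificity at the fixed cutoff; the only stage that reads held-out labels."""
    rows = []
    pred = predictions.set_index("sample_id")
    seeds = _derive_seeds(0 if seed is None else seed, max(1, meta["cohort"].nunique()))
    for k, (split, ids) in enumerate(meta.groupby("cohort")["sample_id"]):
        ids = [s for s in ids if s in pred.index]
        sub = pred.loc[ids]
        y = (meta.loc[ids, "group"] == "PDAC").astype(int).to_numpy()
        if y.min() == y.max():
            continue
        scores = sub["score"].to_numpy()
        roc = stats.roc_auc(scores, y, cutoff=cutoff)
        ci = stats.bootstrap_auc_ci(scores, y, reps=reps, seed=seeds[k])
        tp = int(((scores >= cutoff) & (y == 1)).sum())
        tn = int(((scores < cutoff) & (y == 0)).sum())
        sens_ci = stats.clopper_pearson(tp, roc.n_pos)
        spec_ci = stats.clopper_pearson(tn, roc.n_neg)
        row = {
            "split": split, "n_pos": roc.n_pos, "n_neg": roc.n_neg,
            "auc": round(roc.auc, 4),
            "auc_lo": round(ci.lower, 4), "auc_hi": round(ci.upper, 4),
            "sensitivity": round(roc.sensitivity, 4),
            "sens_lo": round(sens_ci.lower, 4), "sens_hi": round(sens_ci.upper, 4),
            "specificity": round(roc.specificity, 4),
            "spec_lo": round(spec_ci.lower, 4), "spec_hi": round(spec_ci.upper, 4),
        }
        if combined_model is not None:
            ca = meta.loc[ids, "ca19_9"].to_numpy(dtype=float)
            ok = ~np.isnan(ca)
            if ok.sum() >= 4 and np.unique(y[ok]).size == 2:
                combo = combined_model.score(scores[ok], ca[ok])
                row["combined_auc"] = round(stats.mann_whitney_auc(combo, y[ok]), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    """Persist the full input bundle plus every stage output as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    store.write_regions(result.regions, outdir / "regions.bed", outdir / "cpgs.tsv")
    store.write_samples(result.meta, outdir / "samples.tsv")
    hapdir = outdir / "haps"
    hapdir.mkdir(exist_ok=True)
    for sample in result.cohort:
        store.write_haplotypes(sample, result.regions,
                               hapdir / f"{sample.sample_id}.hap.tsv")
    result.truth.regions.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    result.truth.samples.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    result.matrix.to_tsv(outdir / "metrics.tsv")
    discovery.markers_to_frame(result.markers).to_csv(
        outdir / "markers.tsv", sep="\t", index=False)
    (outdir / "model.json").write_text(result.classifier.to_json())
    result.predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    result.report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    (outdir / "run_log.json").write_text(
        json.dumps(result.config.effective_values(), indent=2, sort_keys=True))
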