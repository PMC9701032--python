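"""Classifier construction over selected methylation markers.

The build follows a fixed recipe: per marker, pick the single measurement
that best discriminates cases from controls (smallest logistic-regression
Wald p, with a chi-square window screen available as an alternative); keep
markers detected in enough training samples; impute residual missingness by
k-nearest-neighbour donors from the training set and scale each marker
robustly by its training median and interquartile range; rank markers by
their selection p-value and grow the marker set by incremental 10-fold
cross-validated SVM selection; finally refit the SVM on all training
samples, map its margin through a logistic link to a [0, 1] score and fix
the decision cutoff on the training ROC.  CA19-9, when available, is folded
in by a logistic model on (classifier score, log10(CA19-9 + 1)).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.impute import KNNImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .metrics import METRICS, MetricMatrix
from .stats import cutoff_at_specificity, mann_whitney_auc, youden_cutoff

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RegionalMeasurement:
    region_id: str
    metric: str
    wald_p: float
    penalized: bool = False  # True when the p came from a ridge refit


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _firth_logistic_wald(x: np.ndarray, y: np.ndarray) -> float:
    """Wald p for the slope of a Firth (Jeffreys-prior) logistic fit.

    Used when the unpenalised fit separates perfectly: the bias-reduction
    penalty keeps the estimate finite and scale-equivariant, so a cleanly
    separating measurement still reports a very small p.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    info = np.eye(2)
    for _ in range(200):
        p = _sigmoid(X @ beta)
        W = p * (1 - p)
        info = X.T @ (X * W[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta += step
        if np.abs(step).max() < 1e-8:
            break
    se = np.sqrt(np.linalg.inv(info)[1, 1])
    z = beta[1] / se
    return float(2 * sps.norm.sf(abs(z)))


def _logistic_wald_p(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Two-sided Wald p for the slope of logit(y) ~ intercept + x.

    Falls back to a ridge refit (flagged) on perfect separation or a
    non-converged / degenerate maximum-likelihood fit.
    """
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        p = float(fit.pvalues[1])
        converged = bool(fit.mle_retvals.get("converged", True))
        separated = fit.llf > -1e-6 or not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e4
        if converged and np.isfinite(p) and not separated \
                and np.abs(fit.params).max() < 1e3:
            return p, False
    except (PerfectSeparationError, np.linalg.LinAlgError):
        pass
    return _firth_logistic_wald(x, y), True


def detected_markers(matrix: MetricMatrix, min_detection: float = 0.90,
                     metric: str = "amf") -> list[str]:
    """Region ids detected (non-missing) in at least ``min_detection`` of samples."""
    vals = matrix.values[metric]
    frac = 1.0 - np.isnan(vals).mean(axis=0)
    return [r for r, f in zip(matrix.region_ids, frac) if f >= min_detection]


def select_measurement(matrix: MetricMatrix, labels: pd.Series,
                       marker: str) -> RegionalMeasurement:
    """Pick the measurement of one marker with the smallest logistic Wald p.

    One single-covariate logistic regression per measurement; ties broken by
    the fixed measurement order amf, mhl, mhl3, umhl, umhl3, mhfm, mhfu.
    """
    labels = labels.reindex(matrix.sample_ids)
    y_all = labels.to_numpy()
    if pd.unique(labels.dropna()).size < 2:
        raise ValueError("labels are constant; nothing to regress")
    j = matrix.region_ids.index(marker)
    best: RegionalMeasurement | None = None
    for metric in METRICS:
        col = matrix.values[metric][:, j]
        ok = ~np.isnan(col) & ~pd.isna(y_all)
        y = (y_all[ok] == _positive_label(labels)).astype(float)
        x = col[ok]
        if ok.sum() < 4 or y.min() == y.max() or x.min() == x.max():
            continue
        p, flagged = _logistic_wald_p(x, y)
        if best is None or p < best.wald_p:
            best = RegionalMeasurement(marker, metric, p, flagged)
    if best is None:
        raise ValueError(f"marker {marker!r}: no measurement with variation in both classes")
    return best


def _positive_label(labels: pd.Series):
    """Case label: 'PDAC' if present, else the lexicographically larger group."""
    uniq = sorted(pd.unique(labels.dropna()))
    if "PDAC" in uniq:
        return "PDAC"
    if set(uniq) <= {0, 1, True, False}:
        return 1
    return uniq[-1]


def chi_square_window_test(values_case: np.ndarray,
                           values_control: np.ndarray) -> tuple[float, float]:
    """Chi-square contingency test on 10 equal-width bins over [0, 1].

    Values land in [0, 0.1), ..., [0.9, 1.0] with 1.0 in the last bin; empty
    bins are dropped so df = non-empty bins - 1.  Fewer than two non-empty
    bins gives p = 1 (no distribution to compare).
    """
    def hist(v: np.ndarray) -> np.ndarray:
        v = v[~np.isnan(v)]
        bins = np.minimum((v * 10).astype(int), 9)
        return np.bincount(bins, minlength=10)

    h_case, h_ctrl = hist(values_case), hist(values_control)
    table = np.vstack([h_case, h_ctrl])
    nonempty = table.sum(axis=0) > 0
    table = table[:, nonempty]
    if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def chi_square_window_select(matrix: MetricMatrix, labels: pd.Series,
                             marker: str) -> tuple[str, float]:
    """Measurement of one marker minimising the windowed chi-square p."""
    labels = labels.reindex(matrix.sample_ids)
    pos = _positive_label(labels)
    case_mask = (labels == pos).to_numpy()
    ctrl_mask = (labels != pos).to_numpy() & ~pd.isna(labels).to_numpy()
    j = matrix.region_ids.index(marker)
    best_metric, best_p = METRICS[0], 1.0
    for metric in METRICS:
        col = matrix.values[metric][:, j]
        _, p = chi_square_window_test(col[case_mask], col[ctrl_mask])
        if p < best_p:
            best_metric, best_p = metric, p
    return best_metric, best_p


# ---------------------------------------------------------------------------
# Preprocessing: KNN imputation + robust scaling


@dataclass
class Preprocessor:
    """Per-marker robust scaling plus KNN imputation anchored in training data.

    Scaling is (x - median) / IQR with parameters learned on training
    samples only; markers with zero training IQR are dropped.  Imputation
    donors are always training samples: a missing value is the mean of the
    values of the k nearest training samples, with distances taken over
    mutually observed markers in the scaled space.
    """

    columns: list[str]
    medians: np.ndarray
    iqrs: np.ndarray
    k: int
    train_scaled: np.ndarray  # scaled training matrix with NaN, the donor pool
    _imputer: KNNImputer | None = field(default=None, repr=False, compare=False)

    def _scale(self, raw: np.ndarray) -> np.ndarray:
        return (raw - self.medians) / self.iqrs

    def _ensure_imputer(self) -> KNNImputer:
        if self._imputer is None:
            imp = KNNImputer(n_neighbors=self.k)
            imp.fit(self.train_scaled)
            self._imputer = imp
        return self._imputer

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        """Scale then impute a samples x markers table of raw values."""
        raw = table[self.columns].to_numpy(dtype=float)
        scaled = self._scale(raw)
        imputer = self._ensure_imputer()
        if np.isnan(scaled).any():
            filled = imputer.transform(scaled)
        else:
            filled = scaled
        return pd.DataFrame(filled, index=table.index, columns=self.columns)


def fit_preprocessor(train: pd.DataFrame, k: int = 5) -> Preprocessor:
    """Learn scaling and the imputation donor pool from training data only."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if train.shape[0] < k + 1:
        raise ValueError("need more training rows than neighbours")
    raw = train.to_numpy(dtype=float)
    medians = np.nanmedian(raw, axis=0)
    q1 = np.nanquantile(raw, 0.25, axis=0)
    q3 = np.nanquantile(raw, 0.75, axis=0)
    iqrs = q3 - q1
    keep = iqrs > 0
    if not keep.all():
        dropped = [c for c, good in zip(train.columns, keep) if not good]
        warnings.warn(f"dropping {len(dropped)} markers with zero training IQR: "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}")
    columns = [c for c, good in zip(train.columns, keep) if good]
    medians, iqrs = medians[keep], iqrs[keep]
    scaled = (raw[:, keep] - medians) / iqrs
    return Preprocessor(columns, medians, iqrs, k, scaled)


# ---------------------------------------------------------------------------
# Incremental cross-validated feature selection and the final SVM


@dataclass
class CvStep:
    marker: str
    cv_auc: float
    accepted: bool


def _cv_folds(y: np.ndarray, folds: int, seed: int | None) -> list[tuple[np.ndarray, np.ndarray]]:
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} samples per class for {folds}-fold CV, have {counts.min()}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _mean_cv_auc(x: np.ndarray, y: np.ndarray,
                 splits: Sequence[tuple[np.ndarray, np.ndarray]],
                 kernel: str, C: float) -> float:
    aucs = []
    for tr, te in splits:
        clf = SVC(kernel=kernel, C=C)
        clf.fit(x[tr], y[tr])
        aucs.append(mann_whitney_auc(clf.decision_function(x[te]), y[te]))
    return float(np.mean(aucs))


def incremental_select(
    train: pd.DataFrame,
    labels: Sequence[int],
    ranked_markers: Sequence[str],
    folds: int = 10,
    seed: int | None = None,
    kernel: str = "linear",
    C: float = 1.0,
) -> tuple[list[str], list[CvStep]]:
    """Grow the marker set greedily under a fixed cross-validation split.

    Markers arrive ranked (ascending selection p-value).  The set starts
    with the top marker; each further marker is accepted iff the mean
    10-fold CV AUC of the SVM on the enlarged set does not fall below the
    current set's mean CV AUC (ties accept).  The fold assignment is fixed
    once from ``seed`` and reused for every evaluation.
    """
    y = np.asarray(labels).astype(int)
    splits = _cv_folds(y, folds, seed)
    ranked = list(ranked_markers)
    if not ranked:
        raise ValueError("no candidate markers")
    selected = [ranked[0]]
    x = train[selected].to_numpy(dtype=float)
    best = _mean_cv_auc(x, y, splits, kernel, C)
    trace = [CvStep(ranked[0], best, True)]
    for marker in ranked[1:]:
        cols = selected + [marker]
        auc = _mean_cv_auc(train[cols].to_numpy(dtype=float), y, splits, kernel, C)
        accept = auc >= best
        trace.append(CvStep(marker, auc, accept))
        if accept:
            selected = cols
            best = auc
    return selected, trace


@dataclass
class TrainedClassifier:
    """Serializable SVM classifier over selected markers.

    The raw SVM margin is squashed through a logistic link fitted on the
    training margins, giving a probability-like score in [0, 1]; ``cutoff``
    applies to that score (score >= cutoff calls a case).
    """

    markers: list[str]                      # "<region_id>:<metric>" columns
    preprocessor: Preprocessor
    kernel: str
    C: float
    dual_coef: np.ndarray
    support_vectors: np.ndarray
    intercept: float
    gamma: float
    platt_a: float
    platt_b: float
    cutoff: float
    cv_trace: list[CvStep]
    seed: int | None

    def _margin(self, x: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            w = self.dual_coef @ self.support_vectors
            return x @ w.ravel() + self.intercept
        if self.kernel == "rbf":
            d2 = ((x[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
            return (np.exp(-self.gamma * d2) @ self.dual_coef.ravel()) + self.intercept
        raise ValueError(f"unsupported kernel {self.kernel!r}")

    def score(self, table: pd.DataFrame) -> np.ndarray:
        """Probability-like scores for raw feature rows.

        Imputation uses every preprocessor column as context; the SVM then
        sees only the selected markers.
        """
        processed = self.preprocessor.apply(table)
        x = processed[self.markers].to_numpy(dtype=float)
        return _sigmoid(self.platt_a * self._margin(x) + self.platt_b)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.score(table) >= self.cutoff).astype(int)

    def to_json(self) -> str:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "markers": self.markers,
            "kernel": self.kernel,
            "C": self.C,
            "dual_coef": self.dual_coef.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "cutoff": self.cutoff,
            "seed": self.seed,
            "cv_trace": [[s.marker, s.cv_auc, s.accepted] for s in self.cv_trace],
            "preprocessor": {
                "columns": self.preprocessor.columns,
                "medians": self.preprocessor.medians.tolist(),
                "iqrs": self.preprocessor.iqrs.tolist(),
                "k": self.preprocessor.k,
                "train_scaled": [
                    [None if np.isnan(v) else v for v in row]
                    for row in self.preprocessor.train_scaled
                ],
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TrainedClassifier":
        d = json.loads(text)
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {d.get('schema_version')!r}")
        pp = d["preprocessor"]
        train_scaled = np.array(
            [[np.nan if v is None else v for v in row] for row in pp["train_scaled"]],
            dtype=float,
        )
        prep = Preprocessor(pp["columns"], np.asarray(pp["medians"], dtype=float),
                            np.asarray(pp["iqrs"], dtype=float), pp["k"], train_scaled)
        return cls(
            markers=d["markers"], preprocessor=prep, kernel=d["kernel"], C=d["C"],
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            intercept=d["intercept"], gamma=d["gamma"],
            platt_a=d["platt_a"], platt_b=d["platt_b"], cutoff=d["cutoff"],
            cv_trace=[CvStep(*row) for row in d["cv_trace"]],
            seed=d["seed"],
        )


def train_classifier(
    train: pd.DataFrame,
    labels: Sequence[int],
    selected_markers: Sequence[str],
    preprocessor: Preprocessor,
    seed: int | None = None,
    kernel: str = "linear",
    C: float = 1.0,
    cv_trace: Sequence[CvStep] = (),
    cutoff_mode: str = "youden",
    fixed_specificity: float = 0.89,
) -> TrainedClassifier:
    """Fit the final SVM on all training samples and fix the score cutoff.

    ``train`` holds preprocessed (scaled + imputed) feature values.  The
    cutoff is set either by Youden's J on the training ROC (default) or at
    the smallest score achieving ``fixed_specificity`` on training controls.
    """
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    x = train[list(selected_markers)].to_numpy(dtype=float)
    clf = SVC(kernel=kernel, C=C)
    clf.fit(x, y)
    margins = clf.decision_function(x)
    platt = LogisticRegression(C=1e6, max_iter=1000)
    platt.fit(margins.reshape(-1, 1), y)
    a = float(platt.coef_[0, 0])
    b = float(platt.intercept_[0])
    scores = _sigmoid(a * margins + b)
    if cutoff_mode == "youden":
        cutoff = youden_cutoff(scores, y)
    elif cutoff_mode == "fixed_specificity":
        cutoff = cutoff_at_specificity(scores, y, fixed_specificity)
    else:
        raise ValueError(f"unknown cutoff mode {cutoff_mode!r}")
    gamma = clf._gamma if hasattr(clf, "_gamma") else 1.0 / x.shape[1]
    return TrainedClassifier(
        markers=list(selected_markers), preprocessor=preprocessor,
        kernel=kernel, C=C,
        dual_coef=clf.dual_coef_.copy(), support_vectors=clf.support_vectors_.copy(),
        intercept=float(clf.intercept_[0]),
        gamma=float(gamma),
        platt_a=a, platt_b=b, cutoff=float(cutoff),
        cv_trace=list(cv_trace), seed=seed,
    )


def feature_table(matrix: MetricMatrix,
                  measurements: Sequence[RegionalMeasurement]) -> pd.DataFrame:
    """Raw samples x markers table using each marker's chosen measurement.

    Columns are named ``<region_id>:<metric>`` so the choice is explicit in
    every downstream artifact.
    """
    cols = {}
    for meas in measurements:
        j = matrix.region_ids.index(meas.region_id)
        cols[f"{meas.region_id}:{meas.metric}"] = matrix.values[meas.metric][:, j]
    return pd.DataFrame(cols, index=matrix.sample_ids)


# ---------------------------------------------------------------------------
# CA19-9 integration


@dataclass
class CombinatorialModel:
    """Logistic model over (classifier score, log10(CA19-9 + 1))."""

    coef_score: float
    coef_ca19_9: float
    intercept: float
    cutoff: float

    def score(self, classifier_scores: np.ndarray, ca19_9: np.ndarray) -> np.ndarray:
        z = (self.intercept
             + self.coef_score * np.asarray(classifier_scores, dtype=float)
             + self.coef_ca19_9 * np.log10(np.asarray(ca19_9, dtype=float) + 1.0))
        return _sigmoid(z)


def combine_ca199(classifier_scores, ca19_9, labels) -> tuple[CombinatorialModel, np.ndarray]:
    """Train the combinatorial logistic model; returns (model, probabilities).

    Samples with missing CA19-9 must be excluded by the caller; the CA19-9
    axis enters as log10(x + 1) to tame its heavy right skew.
    """
    scores = np.asarray(classifier_scores, dtype=float)
    ca = np.asarray(ca19_9, dtype=float)
    y = np.asarray(labels).astype(int)
    if ca.size == 0 or np.isnan(ca).all():
        raise ValueError("no samples with CA19-9 values")
    if np.isnan(ca).any() or np.isnan(scores).any():
        raise ValueError("inputs contain missing values; exclude those samples first")
    X = np.column_stack([scores, np.log10(ca + 1.0)])
    lr = LogisticRegression(C=1e6, max_iter=5000)
    lr.fit(X, y)
    model = CombinatorialModel(
        coef_score=float(lr.coef_[0, 0]),
        coef_ca19_9=float(lr.coef_[0, 1]),
        intercept=float(lr.intercept_[0]),
        cutoff=0.5,
    )
    probs = model.score(scores, ca)
    model.cutoff = youden_cutoff(probs, y)
    return model, probs
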