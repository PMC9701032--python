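import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from haplomark.classify import (
    TrainedClassifier,
    chi_square_window_select,
    chi_square_window_test,
    combine_ca199,
    fit_preprocessor,
    incremental_select,
    select_measurement,
    train_classifier,
)
from haplomark.metrics import METRICS, MetricMatrix
from haplomark.stats import mann_whitney_auc

from conftest import matrix_from_values


def labels_for(matrix, n_case):
    ids = matrix.sample_ids
    return pd.Series(["PDAC"] * n_case + ["Healthy"] * (len(ids) - n_case), index=ids)


def matrix_with_metric_columns(per_metric: dict[str, np.ndarray]) -> MetricMatrix:
    """One region; each metric gets its own column of values."""
    any_col = next(iter(per_metric.values()))
    n = any_col.shape[0]
    values = {m: per_metric[m][:, None].astype(float) for m in METRICS}
    return MetricMatrix([f"s{i:03d}" for i in range(n)], ["m0"], values,
                        np.full((n, 1), 100.0))


class TestSelectMeasurement:
    def test_informative_metric_wins(self, rng):
        n = 60
        y = np.array([1] * 30 + [0] * 30)
        per_metric = {m: np.clip(rng.normal(0.5, 0.15, n), 0, 1) for m in METRICS}
        per_metric["mhl3"] = np.clip(0.3 + 0.4 * y + rng.normal(0, 0.05, n), 0, 1)
        matrix = matrix_with_metric_columns(per_metric)
        meas = select_measurement(matrix, labels_for(matrix, 30), "m0")
        assert meas.metric == "mhl3"
        # cross-check the winning Wald p against an independent GLM fit
        import statsmodels.api as sm
        x = sm.add_constant(per_metric["mhl3"])
        glm = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        if not meas.penalized:
            assert meas.wald_p == pytest.approx(glm.pvalues[1], rel=1e-3)

    def test_tie_broken_by_fixed_metric_order(self, rng):
        col = np.clip(rng.normal(0.5, 0.2, 40), 0, 1)
        matrix = matrix_with_metric_columns({m: col for m in METRICS})
        meas = select_measurement(matrix, labels_for(matrix, 20), "m0")
        assert meas.metric == "amf"

    def test_constant_labels_error(self, rng):
        matrix = matrix_with_metric_columns(
            {m: rng.random(10) for m in METRICS})
        with pytest.raises(ValueError, match="constant"):
            select_measurement(matrix, labels_for(matrix, 10), "m0")

    def test_perfect_separation_flagged_finite_p(self):
        col = np.concatenate([np.full(15, 0.9), np.full(15, 0.1)])
        col += np.linspace(0, 0.05, 30)
        matrix = matrix_with_metric_columns({m: col for m in METRICS})
        meas = select_measurement(matrix, labels_for(matrix, 15), "m0")
        assert meas.penalized
        assert 0 <= meas.wald_p < 0.05


class TestChiSquareWindow:
    def test_identical_distributions_null(self):
        v = np.linspace(0.05, 0.95, 20)
        stat, p = chi_square_window_test(v, v.copy())
        assert stat == 0.0 and p == 1.0

    def test_disjoint_bins_hand_value(self):
        case = np.full(20, 0.05)
        ctrl = np.full(20, 0.95)
        stat, p = chi_square_window_test(case, ctrl)
        assert stat == pytest.approx(40.0)
        assert p == pytest.approx(sps.chi2.sf(40.0, df=1))
        assert p < 1e-9

    def test_value_one_lands_in_last_bin(self):
        stat, _ = chi_square_window_test(np.array([1.0] * 5),
                                         np.array([0.95] * 5))
        assert stat == 0.0  # both in bin [0.9, 1.0]

    def test_single_nonempty_bin_p_one(self):
        _, p = chi_square_window_test(np.array([0.55] * 8), np.array([0.52] * 8))
        assert p == 1.0

    def test_select_returns_min_p_metric(self, rng):
        y = np.array([1] * 20 + [0] * 20)
        per_metric = {m: np.clip(rng.normal(0.5, 0.05, 40), 0, 1) for m in METRICS}
        per_metric["umhl"] = 0.05 + 0.9 * y
        matrix = matrix_with_metric_columns(per_metric)
        metric, p = chi_square_window_select(matrix, labels_for(matrix, 20), "m0")
        assert metric == "umhl" and p < 1e-6


class TestPreprocessor:
    def test_scaling_hand_arithmetic(self):
        train = pd.DataFrame({"a": [0.1, 0.2, 0.3, 0.4, 0.5],
                              "b": [0.0, 0.25, 0.5, 0.75, 1.0]})
        prep = fit_preprocessor(train, k=2)
        out = prep.apply(pd.DataFrame({"a": [0.5], "b": [0.5]}))
        # column a: median 0.3, IQR 0.2 -> 0.5 scales to 1.0
        assert out["a"].iloc[0] == pytest.approx(1.0)
        assert out["b"].iloc[0] == pytest.approx(0.0)

    def test_no_missing_is_identity_up_to_scaling(self, rng):
        train = pd.DataFrame(rng.random((12, 3)), columns=list("abc"))
        prep = fit_preprocessor(train, k=3)
        out = prep.apply(train)
        manual = (train[prep.columns] - prep.medians) / prep.iqrs
        np.testing.assert_allclose(out.to_numpy(), manual.to_numpy())

    def test_zero_iqr_marker_dropped_with_warning(self, rng):
        train = pd.DataFrame({"flat": np.full(10, 0.7),
                              "ok": rng.random(10)})
        with pytest.warns(UserWarning, match="zero training IQR"):
            prep = fit_preprocessor(train, k=2)
        assert prep.columns == ["ok"]

    def test_missing_value_imputed_from_neighbours(self, rng):
        base = rng.random((20, 4))
        train = pd.DataFrame(base, columns=list("abcd"))
        prep = fit_preprocessor(train, k=5)
        query = train.iloc[[3]].copy()
        query.loc[:, "d"] = np.nan
        out = prep.apply(query)
        scaled_truth = (base[3, 3] - prep.medians[3]) / prep.iqrs[3]
        # imputed from neighbours, so close to (not exactly) the hidden value
        assert abs(out["d"].iloc[0] - scaled_truth) < 2.0
        assert np.isfinite(out.to_numpy()).all()

    def test_too_few_rows_for_k_raises(self):
        with pytest.raises(ValueError):
            fit_preprocessor(pd.DataFrame({"a": [0.1, 0.2]}), k=5)


class TestIncrementalSelect:
    def _table(self, rng, n=100, informative=0, noise=0, delta=0.5):
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        cols = {}
        for j in range(informative):
            cols[f"inf{j}"] = y * delta + rng.normal(0, 0.25, n)
        for j in range(noise):
            cols[f"noise{j}"] = rng.normal(0, 1.0, n)
        return pd.DataFrame(cols), y

    def test_single_candidate(self, rng):
        table, y = self._table(rng, informative=1)
        selected, trace = incremental_select(table, y, ["inf0"], folds=10, seed=0)
        assert selected == ["inf0"] and len(trace) == 1 and trace[0].accepted

    def test_noise_duplicates_mostly_rejected(self, rng):
        accepted = 0
        trials = 0
        for seed in range(5):
            table, y = self._table(rng, informative=1, noise=4)
            ranked = ["inf0"] + [f"noise{j}" for j in range(4)]
            selected, trace = incremental_select(table, y, ranked, folds=10,
                                                 seed=seed)
            accepted += sum(s.accepted for s in trace[1:])
            trials += len(trace) - 1
        assert accepted / trials < 0.5

    def test_recovers_informative_markers(self, rng):
        table, y = self._table(rng, n=100, informative=5, noise=55, delta=0.5)
        ranked = [f"inf{j}" for j in range(5)] + [f"noise{j}" for j in range(55)]
        selected, _ = incremental_select(table, y, ranked, folds=10, seed=1)
        assert sum(1 for m in selected if m.startswith("inf")) >= 4

    def test_too_few_samples_for_folds(self, rng):
        table, y = self._table(rng, n=10, informative=1)
        with pytest.raises(ValueError, match="10-fold"):
            incremental_select(table, y, ["inf0"], folds=10, seed=0)


class TestTrainClassifier:
    def _fit(self, rng, n=80, sep=3.0):
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        table = pd.DataFrame({
            "a": y * sep + rng.normal(0, 1, n),
            "b": y * sep + rng.normal(0, 1, n),
        })
        prep = fit_preprocessor(table, k=3)
        proc = prep.apply(table)
        clf = train_classifier(proc, y, ["a", "b"], prep, seed=0)
        return clf, table, y

    def test_separable_training_auc_one(self, rng):
        clf, table, y = self._fit(rng, sep=30.0)
        scores = clf.score(table)
        assert mann_whitney_auc(scores, y) == 1.0
        assert (scores[y == 1] >= clf.cutoff).all()
        assert (scores[y == 0] < clf.cutoff).all()

    def test_label_permutation_near_chance(self, rng):
        n = 80
        y = np.array([1] * 40 + [0] * 40)
        table = pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["a", "b"])
        prep = fit_preprocessor(table, k=3)
        clf = train_classifier(prep.apply(table), y, ["a", "b"], prep, seed=0)
        auc = mann_whitney_auc(clf.score(table), y)
        assert abs(auc - 0.5) < 0.12 + 0.15  # training fit inflates slightly

    def test_serialization_round_trip(self, rng):
        clf, table, _ = self._fit(rng)
        clone = TrainedClassifier.from_json(clf.to_json())
        np.testing.assert_allclose(clone.score(table), clf.score(table),
                                   atol=1e-9)
        assert clone.cutoff == clf.cutoff

    def test_single_class_labels_error(self, rng):
        table = pd.DataFrame({"a": rng.random(10)})
        prep = fit_preprocessor(table, k=2)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(prep.apply(table), np.ones(10, dtype=int), ["a"], prep)


class TestCombineCa199:
    def test_uninformative_ca_keeps_classifier_auc(self, rng):
        n = 120
        y = np.array([1] * 60 + [0] * 60)
        scores = np.clip(0.3 + 0.4 * y + rng.normal(0, 0.1, n), 0, 1)
        ca = np.full(n, 10.0)
        _, probs = combine_ca199(scores, ca, y)
        assert mann_whitney_auc(probs, y) == pytest.approx(
            mann_whitney_auc(scores, y), abs=0.02)

    def test_complementary_signals_beat_parents(self, rng):
        n = 400
        y = np.array([1] * 200 + [0] * 200)
        scores = 1 / (1 + np.exp(-(y * 1.2 + rng.normal(0, 1, n))))
        ca = np.exp(y * 1.2 + rng.normal(0, 1, n) + 2)
        train = np.arange(n) % 2 == 0
        model, _ = combine_ca199(scores[train], ca[train], y[train])
        held = ~train
        combined = model.score(scores[held], ca[held])
        auc_c = mann_whitney_auc(combined, y[held])
        assert auc_c > max(mann_whitney_auc(scores[held], y[held]),
                           mann_whitney_auc(np.log10(ca[held] + 1), y[held]))

    def test_constant_score_reduces_to_ca(self, rng):
        n = 100
        y = np.array([1] * 50 + [0] * 50)
        ca = np.exp(y * 2 + rng.normal(0, 0.5, n) + 1)
        _, probs = combine_ca199(np.full(n, 0.5), ca, y)
        assert mann_whitney_auc(probs, y) == pytest.approx(
            mann_whitney_auc(np.log10(ca + 1), y), abs=1e-6)

    def test_all_missing_ca_error(self):
        with pytest.raises(ValueError):
            combine_ca199(np.array([0.5, 0.6]), np.array([np.nan, np.nan]),
                          np.array([1, 0]))
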