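import numpy as np
import pandas as pd
import pytest

from haplomark.discovery import (
    MarkerRecord,
    assemble_panel,
    differential_mhbs,
    filter_mhbs,
    p2p_selection,
    tss_markers,
)

from _oracles import exact_rank_sum_p
from conftest import make_region, matrix_from_values


class TestFilterMhbs:
    def test_na_rate_strictly_above_threshold_drops(self):
        vals = np.full((20, 2), 0.5)
        vals += np.linspace(0, 0.6, 20)[:, None]  # give both regions variance
        vals[:3, 0] = np.nan  # 15% > 10%
        vals[:2, 1] = np.nan  # exactly 10% -> kept
        matrix = matrix_from_values(np.clip(vals, 0, 1))
        out, report = filter_mhbs(matrix, "amf", max_na_rate=0.10, min_variance=0.0)
        assert out.region_ids == ["r001"]
        assert report.removed_na_rate == 1 and report.removed_low_variance == 0
        assert report.regions_out == report.regions_in - 1

    def test_variance_boundary_is_strict(self, rng):
        col = np.clip(rng.normal(0.5, 0.25, 21), 0, 1)
        exact_var = float(np.var(col, ddof=1))
        matrix = matrix_from_values(col[:, None])
        kept, _ = filter_mhbs(matrix, "amf", min_variance=exact_var)
        assert kept.region_ids == ["r000"]        # var == threshold survives
        dropped, report = filter_mhbs(matrix, "amf",
                                      min_variance=np.nextafter(exact_var, np.inf))
        assert dropped.region_ids == [] and report.removed_low_variance == 1

    def test_constant_region_dropped(self):
        vals = np.column_stack([np.full(10, 0.4), np.linspace(0, 1, 10)])
        out, report = filter_mhbs(matrix_from_values(vals), "amf")
        assert out.region_ids == ["r001"]

    def test_unknown_metric_raises(self):
        with pytest.raises(KeyError):
            filter_mhbs(matrix_from_values(np.zeros((4, 2))), "nope")


class TestDifferentialMhbs:
    def _labels(self, n_case, n_ctrl):
        ids = [f"s{i:03d}" for i in range(n_case + n_ctrl)]
        return pd.Series(["PDAC"] * n_case + ["Healthy"] * n_ctrl, index=ids)

    def test_null_no_selection(self, rng):
        vals = rng.random((30, 80))
        recs = differential_mhbs(matrix_from_values(vals), self._labels(15, 15))
        assert len(recs) <= 4  # ~alpha-level false positives at most

    def test_power_under_planted_shift(self, rng):
        n, true_k, null_k = 15, 50, 450
        vals = rng.normal(0.4, 0.1, size=(2 * n, true_k + null_k))
        vals[:n, :true_k] += 0.4
        vals = np.clip(vals, 0, 1)
        recs = differential_mhbs(matrix_from_values(vals), self._labels(n, n))
        hits = {r.region_id for r in recs}
        true_ids = {f"r{j:03d}" for j in range(true_k)}
        recovered = len(hits & true_ids) / true_k
        assert recovered >= 0.8
        # q-values are BH-monotone in p rank and never below p
        assert all(r.fdr_q >= r.p_value - 1e-12 for r in recs)

    def test_single_region_bh_identity(self):
        vals = np.concatenate([np.linspace(0.0, 0.2, 8), np.linspace(0.5, 0.9, 8)])
        recs = differential_mhbs(matrix_from_values(vals[:, None]),
                                 self._labels(8, 8), alpha=1.0)
        assert recs[0].fdr_q == pytest.approx(recs[0].p_value)

    def test_exact_small_sample_p_matches_enumeration(self):
        x = [0.11, 0.35, 0.52, 0.60, 0.74, 0.83]
        y = [0.05, 0.21, 0.40, 0.47, 0.55, 0.68]
        vals = np.array(x + y)[:, None]
        recs = differential_mhbs(matrix_from_values(vals), self._labels(6, 6),
                                 alpha=1.0)
        assert recs[0].p_value == pytest.approx(exact_rank_sum_p(x, y))

    def test_selections_shrink_with_alpha(self, rng):
        vals = rng.normal(0.5, 0.1, size=(24, 60))
        vals[:12, :20] += 0.25
        matrix = matrix_from_values(np.clip(vals, 0, 1))
        labels = self._labels(12, 12)
        loose = {r.region_id for r in differential_mhbs(matrix, labels, alpha=0.1)}
        tight = {r.region_id for r in differential_mhbs(matrix, labels, alpha=0.01)}
        assert tight <= loose

    def test_sparse_region_skipped(self, rng):
        vals = rng.random((12, 2))
        vals[:10, 0] = np.nan  # only 2 non-missing in the case group
        recs = differential_mhbs(matrix_from_values(vals), self._labels(6, 6),
                                 alpha=1.0)
        assert {r.region_id for r in recs} == {"r001"}


class TestP2PSelection:
    def _matrix(self, rng, n_strong=0, delta=0.5, n_regions=120, n_cases=25,
                n_ctrl=30):
        vals = rng.normal(0.4, 0.08, size=(n_cases + n_ctrl, n_regions))
        vals[:n_cases, :n_strong] += delta
        matrix = matrix_from_values(np.clip(vals, 0, 1))
        cases = matrix.sample_ids[:n_cases]
        controls = matrix.sample_ids[n_cases:]
        return matrix, cases, controls

    def test_zero_iterations_empty(self, rng):
        matrix, cases, controls = self._matrix(rng)
        assert p2p_selection(matrix, cases, controls, iters=0, seed=1) == []

    def test_strong_markers_recovered(self, rng):
        matrix, cases, controls = self._matrix(rng, n_strong=10)
        recs = p2p_selection(matrix, cases, controls, iters=40, count_min=24,
                             seed=7, n_trees=100)
        strong = {f"r{j:03d}" for j in range(10)}
        assert strong <= {r.region_id for r in recs}
        assert all(r.selection_count > 24 for r in recs)

    def test_deterministic_under_seed(self, rng):
        matrix, cases, controls = self._matrix(rng, n_strong=5)
        a = p2p_selection(matrix, cases, controls, iters=15, count_min=5,
                          seed=3, n_trees=50)
        b = p2p_selection(matrix, cases, controls, iters=15, count_min=5,
                          seed=3, n_trees=50)
        assert [(r.region_id, r.selection_count) for r in a] == \
               [(r.region_id, r.selection_count) for r in b]

    def test_too_few_samples_raises(self, rng):
        matrix, cases, controls = self._matrix(rng, n_cases=25)
        with pytest.raises(ValueError):
            p2p_selection(matrix, cases[:10], controls, iters=5, seed=1)


class TestTssMarkers:
    @pytest.fixture
    def annotation(self, tmp_path):
        tss = tmp_path / "tss.bed"
        tss.write_text(
            "chr1\t10000\t10001\tGENEA\t0\t+\n"
            "chr1\t50000\t50001\tGENEB\t0\t-\n"
        )
        genes = tmp_path / "genes.txt"
        genes.write_text("GENEA\nGENEB\nGENEC\n")
        return tss, genes

    def _region(self, start, end, rid="m1"):
        from haplomark.store import RegionDef
        return RegionDef(rid, "chr1", start, end, (start + 1,))

    def test_downstream_window_hit(self, annotation):
        tss, genes = annotation
        recs = tss_markers([self._region(10480, 10530)], tss, genes)
        assert [r.region_id for r in recs] == ["m1"]
        assert recs[0].source == "literature"

    def test_beyond_downstream_boundary_missed(self, annotation):
        tss, genes = annotation
        assert tss_markers([self._region(11200, 11300)], tss, genes) == []

    def test_minus_strand_window_reflected(self, annotation):
        tss, genes = annotation
        # upstream of a '-' gene = higher coordinates
        assert tss_markers([self._region(51200, 51300, "m2")], tss, genes) != []
        assert tss_markers([self._region(48400, 48500, "m3")], tss, genes) == []


class TestAssemblePanel:
    def _recs(self, ids, source):
        return [MarkerRecord(i, source) for i in ids]

    def test_disjoint_intersection_empty(self):
        panel = assemble_panel(self._recs(["a", "b"], "T2T"),
                               self._recs(["c"], "T2P"), [], [])
        assert panel == []

    def test_marker_in_all_sources_deduplicated(self):
        panel = assemble_panel(self._recs(["a"], "T2T"), self._recs(["a"], "T2P"),
                               self._recs(["a"], "P2P"),
                               self._recs(["a"], "literature"))
        assert len(panel) == 1
        assert panel[0].source == "P2P+T2P+T2T+literature"

    def test_set_arithmetic_on_constructed_flow(self):
        t2t = self._recs([f"t{i}" for i in range(100)], "T2T")
        t2p = self._recs([f"t{i}" for i in range(76)] +
                         [f"x{i}" for i in range(50)], "T2P")
        lit = self._recs([f"t{i}" for i in range(60, 102)], "literature")
        p2p = self._recs([f"t{i}" for i in range(70, 80)] +
                         [f"p{i}" for i in range(43)], "P2P")
        panel = assemble_panel(t2t, t2p, p2p, lit)
        # (T2T n T2P) = t0..t75; (T2T n lit) = t60..t99; P2P adds t70..t79, p0..p42
        expected = {f"t{i}" for i in range(100)} | {f"p{i}" for i in range(43)}
        assert {r.region_id for r in panel} == expected
        assert [r.region_id for r in panel] == sorted(expected)
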