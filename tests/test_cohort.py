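"""Group statistics, feature assembly, and two-feature classification."""

import numpy as np
import pytest

from lso_ephys import cohort as coh
from lso_ephys.core_io import CellRecord, ValidationError
from lso_ephys.vm_features import FeatureVector


class TestPooledT:
    def test_reproduces_cutoff_comparison(self):
        """Printed group summaries give t_10 = 6.83 for the spectral cutoff."""
        a = coh.GroupSummary(5, 528.7, 66.5)
        b = coh.GroupSummary(7, 131.4, 15.5)
        res = coh.pooled_t_from_summaries(a, b)
        assert res.statistic == pytest.approx(6.83, abs=0.01)
        assert res.df == 10
        assert res.p_two_tailed < 1e-4

    def test_reproduces_ap_amplitude_comparison(self):
        a = coh.GroupSummary(5, 28.3, 5.2)
        b = coh.GroupSummary(7, 66.3, 4.5)
        res = coh.pooled_t_from_summaries(a, b)
        assert res.statistic == pytest.approx(-5.48, rel=0.01)

    def test_identical_groups_give_zero(self):
        a = coh.GroupSummary(5, 10.0, 1.0)
        res = coh.pooled_t_from_summaries(a, a)
        assert res.statistic == 0.0

    def test_sample_path_equals_summary_path(self):
        rng = np.random.default_rng(9)
        x = rng.normal(5, 2, 9)
        y = rng.normal(7, 2, 12)
        from_samples = coh.pooled_t_from_samples(x, y)
        from_summ = coh.pooled_t_from_summaries(coh.summarize(x), coh.summarize(y))
        assert from_samples.statistic == pytest.approx(
            from_summ.statistic, rel=1e-12
        )
        # and both agree with the reference implementation
        from scipy import stats

        ref = stats.ttest_ind(x, y, equal_var=True)
        assert from_samples.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert from_samples.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)


class TestHedgesG:
    def test_reproduces_cutoff_effect_size(self):
        g = coh.hedges_g(
            coh.GroupSummary(5, 528.7, 66.5), coh.GroupSummary(7, 131.4, 15.5)
        )
        assert g == pytest.approx(4.00, abs=0.005)

    def test_reproduces_ap_amplitude_effect_size(self):
        g = coh.hedges_g(
            coh.GroupSummary(5, 28.3, 5.2), coh.GroupSummary(7, 66.3, 4.5)
        )
        assert abs(g) == pytest.approx(3.21, rel=0.01)

    def test_equal_means_zero(self):
        a = coh.GroupSummary(5, 10.0, 1.0)
        assert coh.hedges_g(a, a) == 0.0

    def test_small_sample_correction_shrinks(self):
        a = coh.GroupSummary(5, 528.7, 66.5)
        b = coh.GroupSummary(7, 131.4, 15.5)
        assert abs(coh.hedges_g(a, b, corrected=True)) < abs(coh.hedges_g(a, b))


class TestPearson:
    def test_perfect_line(self):
        res = coh.pearson_r([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_two_tailed < 1e-6

    def test_printed_pair_r_and_p(self):
        """r = -0.64 at n = 11 corresponds to p ~ 0.035."""
        rng = np.random.default_rng(3)
        # construct 11 pairs with sample correlation exactly -0.64
        x = rng.normal(size=11)
        y = rng.normal(size=11)
        x = (x - x.mean()) / x.std()
        y = y - y.mean()
        y -= x * np.dot(x, y) / np.dot(x, x)  # orthogonalize
        y /= y.std()
        r_target = -0.64
        y = r_target * x + np.sqrt(1 - r_target**2) * y
        res = coh.pearson_r(x, y)
        assert res.statistic == pytest.approx(-0.64, abs=1e-9)
        assert res.df == 9
        assert res.p_two_tailed == pytest.approx(0.035, abs=0.003)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        res = coh.pearson_r(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert res.statistic == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            coh.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _fv(cid, fc, amp):
    return FeatureVector(cell_id=cid, upper_cutoff=fc, ap_amplitude=amp)


def _toy_features(seed=1, n_p=6, n_np=6):
    rng = np.random.default_rng(seed)
    fvs, truth = [], []
    for i in range(n_p):
        fvs.append(_fv(f"p{i}", 10 ** rng.normal(2.7, 0.1), rng.normal(28, 5)))
        truth.append("principal")
    for i in range(n_np):
        fvs.append(_fv(f"n{i}", 10 ** rng.normal(2.0, 0.1), rng.normal(66, 5)))
        truth.append("non_principal")
    return fvs, truth


class TestClusterCells:
    def test_separates_toy_groups(self):
        fvs, truth = _toy_features()
        res = coh.cluster_cells(fvs)
        assert res.labels == truth

    def test_order_invariance(self):
        fvs, truth = _toy_features(seed=2)
        res_fwd = coh.cluster_cells(fvs)
        res_rev = coh.cluster_cells(fvs[::-1])
        assert res_fwd.labels == res_rev.labels[::-1]

    def test_affine_rescaling_invariance(self):
        """z-scoring makes labels invariant to per-feature affine rescaling."""
        fvs, _ = _toy_features(seed=3)
        scaled = [
            _fv(f.cell_id, f.upper_cutoff ** 1.0 * 1e3, 0.1 * f.ap_amplitude + 40)
            for f in fvs
        ]
        assert coh.cluster_cells(fvs).labels == coh.cluster_cells(scaled).labels

    def test_anchor_assignment_of_unlabeled_cells(self):
        """5 + 7 anchored cells pull 9 unlabeled ones; none unassignable."""
        rng = np.random.default_rng(1)
        fvs, anchors = [], []
        for i in range(5):
            fvs.append(_fv(f"p{i}", 10 ** rng.normal(2.7, 0.1), rng.normal(28, 5)))
            anchors.append("principal")
        for i in range(7):
            fvs.append(_fv(f"n{i}", 10 ** rng.normal(2.1, 0.1), rng.normal(66, 5)))
            anchors.append("non_principal")
        for i in range(9):
            is_p = i % 2 == 0
            fvs.append(
                _fv(
                    f"u{i}",
                    10 ** rng.normal(2.7 if is_p else 2.1, 0.1),
                    rng.normal(28 if is_p else 66, 5),
                )
            )
            anchors.append(None)
        res = coh.cluster_cells(fvs, anchors=anchors)
        assert "unassignable" not in res.labels
        for i in range(9):
            expect = "principal" if i % 2 == 0 else "non_principal"
            assert res.labels[12 + i] == expect

    def test_identical_points_with_conflicting_anchors_flagged(self):
        fvs = [_fv(str(i), 300.0, 30.0) for i in range(4)]
        anchors = ["principal", "principal", "non_principal", "non_principal"]
        res = coh.cluster_cells(fvs, anchors=anchors)
        assert np.allclose(res.confidence, 0.0)

    def test_too_few_cells_rejected(self):
        fvs, _ = _toy_features(n_p=2, n_np=1)
        with pytest.raises(ValidationError):
            coh.cluster_cells(fvs)


class TestClassifyCohort:
    def test_single_cell_cohort_unassignable(self):
        from lso_ephys import synth

        cells = synth.gen_cohort(
            1, 0, seed=3, include_protocols=("spontaneous", "ipsi_tone")
        )
        records = [c for c, _ in cells]
        fvs = [coh.extract_features(c) for c in records]
        res = coh.classify_cohort(records, fvs)
        assert res.labels == ["unassignable"]


class TestExtractFeatures:
    def test_missing_spontaneous_named(self):
        cell = CellRecord(cell_id="nospont")
        with pytest.raises(ValidationError, match="spontaneous"):
            coh.extract_features(cell)

    def test_features_from_synthetic_cells(self, small_cohort):
        for cell, truths in small_cohort:
            fv = coh.extract_features(cell)
            assert fv.complete_for_classification()
            if truths["_params"].class_label == "principal":
                assert fv.upper_cutoff > 150.0
                assert fv.ap_amplitude < 50.0
            else:
                assert fv.upper_cutoff < 150.0
                assert fv.ap_amplitude > 40.0

    def test_optional_protocols_absent_not_defaulted(self, small_cohort):
        cell, _ = small_cohort[0]
        fv = coh.extract_features(cell)  # no ILD / step protocols generated
        assert fv.r_in_steady is None
        assert fv.sustained_hyperpol is None
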