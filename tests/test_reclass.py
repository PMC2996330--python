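import numpy as np
import pytest
from scipy import stats

from liabpred import (
    DiseaseModel,
    NestedModels,
    conditional_moments,
    idi,
    joint_conditional_moments,
    liability_threshold,
    reclassification_table,
    risk_category_cutpoints,
    risk_summary,
    weighted_nri,
)
from liabpred.reclass import BivariateParams, ReclassificationResult, _rect_prob

THRESHOLDS = (0.06, 0.2)


def risk_at_liability(z: float, k: float, v: float) -> float:
    """Absolute risk conditional on measurable liability z under variance v."""
    t = liability_threshold(k)
    return float(stats.norm.sf((t - z) / np.sqrt(1.0 - v)))


class TestCutpoints:
    def test_zero_variance_cutpoint_finite_and_consistent(self):
        k = 0.08
        z = risk_category_cutpoints(k, 0.0, [k])[0]
        assert z == pytest.approx(
            liability_threshold(k) + stats.norm.ppf(k), abs=1e-12)
        assert risk_at_liability(z, k, 0.0) == pytest.approx(k, abs=1e-12)

    def test_inverse_identity(self):
        z = risk_category_cutpoints(0.05, 0.1, [0.2])[0]
        assert risk_at_liability(z, 0.05, 0.1) == pytest.approx(0.2, abs=1e-10)

    def test_strictly_increasing(self):
        cuts = risk_category_cutpoints(0.05, 0.1, [0.01, 0.06, 0.2, 0.5])
        assert np.all(np.diff(cuts) > 0.0)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            risk_category_cutpoints(0.05, 0.1, [0.2, 0.06])
        with pytest.raises(ValueError):
            risk_category_cutpoints(0.05, 0.1, [0.0, 0.2])


class TestNestedModels:
    def test_default_covariance_is_v_old(self):
        assert NestedModels(0.1, 0.05, 0.15).cov == 0.05

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            NestedModels(0.1, 0.1, 0.1, cov_old_new=-0.09)


class TestJointConditionalMoments:
    def test_identical_models_perfectly_correlated(self):
        case, ctrl = joint_conditional_moments(NestedModels(0.1, 0.1, 0.1))
        for par in (case, ctrl):
            s = np.sqrt(np.diag(par.cov))
            rho = par.cov[0, 1] / (s[0] * s[1])
            assert rho == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_oracle(self):
        # 1e7 liability triples partitioned by case status
        k, v_old, v_new = 0.05, 0.05, 0.1
        rng = np.random.default_rng(2024)
        n = 10_000_000
        l_old = rng.normal(0.0, np.sqrt(v_old), n)
        l_add = rng.normal(0.0, np.sqrt(v_new - v_old), n)
        l_new = l_old + l_add
        overall = l_new + rng.normal(0.0, np.sqrt(1.0 - v_new), n)
        case_mask = overall > liability_threshold(k)
        case, ctrl = joint_conditional_moments(
            NestedModels(k, v_old, v_new))
        for par, mask in ((case, case_mask), (ctrl, ~case_mask)):
            sample = np.column_stack([l_old[mask], l_new[mask]])
            assert np.allclose(par.mean, sample.mean(axis=0), atol=2e-3)
            assert np.allclose(par.cov, np.cov(sample.T), atol=2e-3)

    def test_marginal_consistency_with_univariate_moments(self):
        models = NestedModels(0.05, 0.05, 0.1)
        case, ctrl = joint_conditional_moments(models)
        uni_new = conditional_moments(DiseaseModel(models.k, models.v_new))
        assert case.mean[1] == pytest.approx(uni_new.mean_meas_case, abs=1e-12)
        assert case.cov[1, 1] == pytest.approx(uni_new.var_meas_case, abs=1e-12)
        uni_old = conditional_moments(DiseaseModel(models.k, models.v_old))
        assert ctrl.mean[0] == pytest.approx(
            uni_old.mean_meas_control, abs=1e-12)
        assert ctrl.cov[0, 0] == pytest.approx(
            uni_old.var_meas_control, abs=1e-12)


class TestReclassificationTable:
    def test_identical_models_stay_on_diagonal(self):
        result = reclassification_table(NestedModels(0.1, 0.1, 0.1), THRESHOLDS)
        assert result.p_up_case == pytest.approx(0.0, abs=1e-9)
        assert result.p_down_control == pytest.approx(0.0, abs=1e-9)
        assert result.nri == pytest.approx(0.0, abs=1e-9)

    def test_reference_nri_k005(self):
        result = reclassification_table(
            NestedModels(0.05, 0.05, 0.1), THRESHOLDS)
        assert result.nri == pytest.approx(0.099, abs=0.002)

    def test_reference_nri_k01(self):
        result = reclassification_table(
            NestedModels(0.1, 0.05, 0.15), THRESHOLDS)
        assert result.nri == pytest.approx(0.306, abs=0.005)

    def test_matrices_normalised(self):
        result = reclassification_table(
            NestedModels(0.05, 0.1, 0.2), THRESHOLDS)
        assert result.case_matrix.sum() == pytest.approx(1.0, abs=1e-6)
        assert result.control_matrix.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(result.case_matrix >= 0.0)

    def test_row_sums_match_univariate_occupancy(self):
        models = NestedModels(0.05, 0.05, 0.15)
        result = reclassification_table(models, THRESHOLDS)
        cuts_old = risk_category_cutpoints(models.k, models.v_old, THRESHOLDS)
        uni = conditional_moments(DiseaseModel(models.k, models.v_old))
        edges = np.concatenate([[-np.inf], cuts_old, [np.inf]])
        occupancy = np.diff(stats.norm.cdf(
            (edges - uni.mean_meas_case) / np.sqrt(uni.var_meas_case)))
        assert np.allclose(result.case_matrix.sum(axis=1), occupancy, atol=1e-6)

    def test_mixture_matches_unconditioned_bivariate(self):
        # The case/control transition matrices are built under the binormal
        # working approximation (exact PA moments, approximate normal shape),
        # so the K-weighted mixture reproduces the exactly-normal
        # unconditioned rectangle masses only up to the approximation error
        # (~3e-4 here), not to quadrature precision.
        models = NestedModels(0.05, 0.05, 0.1)
        result = reclassification_table(models, THRESHOLDS)
        sigma_m = np.array([[models.v_old, models.cov],
                            [models.cov, models.v_new]])
        par = BivariateParams(mean=np.zeros(2), cov=sigma_m)
        cuts_old = risk_category_cutpoints(models.k, models.v_old, THRESHOLDS)
        cuts_new = risk_category_cutpoints(models.k, models.v_new, THRESHOLDS)
        e_old = np.concatenate([[-np.inf], cuts_old, [np.inf]])
        e_new = np.concatenate([[-np.inf], cuts_new, [np.inf]])
        k = models.k
        for i in range(3):
            for j in range(3):
                expected = _rect_prob(
                    par,
                    np.array([e_old[i], e_new[j]]),
                    np.array([e_old[i + 1], e_new[j + 1]]))
                mixed = (k * result.case_matrix[i, j]
                         + (1 - k) * result.control_matrix[i, j])
                assert mixed == pytest.approx(expected, abs=1e-3)

    def test_nri_vanishes_and_grows_with_added_variance(self):
        base = 0.05
        nris = [
            reclassification_table(
                NestedModels(0.1, base, base + delta), THRESHOLDS).nri
            for delta in (1e-6, 0.05, 0.1)
        ]
        assert abs(nris[0]) < 1e-3
        assert nris[0] < nris[1] < nris[2]

    def test_requires_thresholds(self):
        with pytest.raises(ValueError):
            reclassification_table(NestedModels(0.1, 0.05, 0.1), ())
        with pytest.raises(ValueError):
            reclassification_table(NestedModels(0.1, 0.05, 0.1), (0.06, 1.2))


class TestWeightedNri:
    @pytest.fixture
    def result(self):
        return reclassification_table(NestedModels(0.1, 0.05, 0.15), THRESHOLDS)

    def test_unit_weights_reduce_to_nri(self, result):
        assert weighted_nri(result) == pytest.approx(result.nri, abs=1e-12)

    def test_case_side_only(self, result):
        value = weighted_nri(result, weights=(1, 1, 0, 0))
        assert value == pytest.approx(
            result.p_up_case - result.p_down_case, abs=1e-12)

    def test_shift_scores_amplify_multi_category_moves(self):
        # hand-built table with a two-step downward move within cases
        case = np.array([[0.4, 0.0, 0.0],
                         [0.0, 0.3, 0.0],
                         [0.3, 0.0, 0.0]])
        control = np.eye(3) / 3.0
        result = ReclassificationResult(
            thresholds=THRESHOLDS, case_matrix=case, control_matrix=control)
        plain = weighted_nri(result)
        scored = weighted_nri(result, category_shift_scores=True)
        assert abs(scored) > abs(plain)
        assert scored == pytest.approx(-0.6, abs=1e-12)  # 2 * 0.3 down-moves


class TestIdi:
    def test_identical_models(self):
        assert idi(NestedModels(0.1, 0.1, 0.1)) == pytest.approx(0.0, abs=1e-12)

    def test_reference_value(self):
        assert idi(NestedModels(0.1, 0.1, 0.2)) == pytest.approx(
            0.043, abs=0.001)

    def test_cross_table_consistency(self):
        # slope difference from the dispersion summaries equals the IDI
        slope_hi = risk_summary(DiseaseModel(0.05, 0.2)).discrimination_slope
        slope_lo = risk_summary(DiseaseModel(0.05, 0.1)).discrimination_slope
        value = idi(NestedModels(0.05, 0.1, 0.2))
        assert value == pytest.approx(slope_hi - slope_lo, abs=1e-10)
        assert value == pytest.approx(0.032, abs=0.001)
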