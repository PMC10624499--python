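"""Estimators against closed forms, independent WLS/GLS oracles, and identities."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from lipidmr.errors import (
    CollinearityError,
    ConditioningError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from lipidmr.estimators import (
    FIXED,
    MULT_RANDOM,
    MRInput,
    egger,
    ivw,
    ivw_correlated,
    mvmr_ivw,
    wald_ratio,
)
from lipidmr.sumstats import LDMatrix

from conftest import identity_ld, make_harmonized, random_harmonized


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(0.5, 0.1, 0.1, 0.05)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.ci_low < est.beta < est.ci_high

    def test_null_outcome_effect(self):
        est = wald_ratio(0.5, 0.1, 0.0, 0.05)
        assert est.beta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_zero_exposure_effect_is_an_error(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.1, 0.1, 0.05)

    def test_negative_exposure_effect_se_positive(self):
        est = wald_ratio(-0.5, 0.1, 0.1, 0.05)
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)


class TestIVW:
    def test_equal_weight_closed_form(self):
        h = make_harmonized([1, 1], [0.1, 0.1], [0.1, 0.3], [1, 1])
        est, het = ivw(MRInput(h), FIXED)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(1 / np.sqrt(2))
        assert het.Q == pytest.approx(0.02)
        assert het.dof == 1

    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.5], [0.1], [0.1], [0.05])
        est, _ = ivw(MRInput(h))
        ref = wald_ratio(0.5, 0.1, 0.1, 0.05)
        assert est.beta == ref.beta and est.se == ref.se and est.pvalue == ref.pvalue

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_harmonized(rng, 10)
        est, het = ivw(MRInput(h), FIXED)
        # independent route: statsmodels weighted regression through origin
        res = sm.WLS(h.beta_y, h.beta_x[:, None], weights=1.0 / h.se_y**2).fit()
        assert est.beta == pytest.approx(res.params[0], abs=1e-10)
        # fixed-effect se strips statsmodels' estimated residual scale
        assert est.se == pytest.approx(res.bse[0] / np.sqrt(res.scale), abs=1e-10)
        assert het.Q == pytest.approx(res.ssr, abs=1e-9)

    def test_random_effects_se_never_smaller(self, rng):
        for _ in range(20):
            h = random_harmonized(rng, 8)
            fixed, _ = ivw(MRInput(h), FIXED)
            rand, _ = ivw(MRInput(h), MULT_RANDOM)
            assert rand.se >= fixed.se - 1e-15
            assert rand.re_scale >= 1.0

    def test_q_zero_when_wald_ratios_identical(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, 0.1 * bx, 0.3 * bx, [0.1, 0.2, 0.05])
        _, het = ivw(MRInput(h), FIXED)
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.I2_percent == 0.0

    def test_allele_recoding_invariance(self, rng):
        h = random_harmonized(rng, 12)
        est1, _ = ivw(MRInput(h))
        flip = rng.random(12) < 0.5
        h2 = make_harmonized(
            np.where(flip, -h.beta_x, h.beta_x),
            h.se_x,
            np.where(flip, -h.beta_y, h.beta_y),
            h.se_y,
        )
        est2, _ = ivw(MRInput(h2))
        assert est2.beta == pytest.approx(est1.beta, abs=1e-12)
        assert est2.se == pytest.approx(est1.se, abs=1e-12)


class TestIVWCorrelated:
    def test_identity_ld_equals_independent(self, rng):
        for _ in range(10):
            h = random_harmonized(rng, 7)
            est_i, het_i = ivw(MRInput(h))
            est_c, het_c = ivw_correlated(MRInput(h, ld=identity_ld(7)))
            assert est_c.beta == pytest.approx(est_i.beta, abs=1e-10)
            assert est_c.se == pytest.approx(est_i.se, abs=1e-10)
            assert het_c.Q == pytest.approx(het_i.Q, abs=1e-10)

    def test_consistent_effects_give_zero_q(self):
        h = make_harmonized([1, 1], [0.1, 0.1], [0.2, 0.2], [1, 1])
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        est, het = ivw_correlated(MRInput(h, ld=ld))
        assert est.beta == pytest.approx(0.2)
        assert het.Q == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_gls_oracle_ar1(self, seed):
        rng = np.random.default_rng(100 + seed)
        J = 5
        h = random_harmonized(rng, J)
        d = np.abs(np.subtract.outer(np.arange(J), np.arange(J)))
        r = 0.6**d
        ld = LDMatrix(h.variant_ids, r)
        est, het = ivw_correlated(MRInput(h, ld=ld), FIXED)
        omega = np.outer(h.se_y, h.se_y) * r
        res = sm.GLS(h.beta_y, h.beta_x[:, None], sigma=omega).fit()
        assert est.beta == pytest.approx(res.params[0], abs=1e-9)
        assert est.se == pytest.approx(res.bse[0] / np.sqrt(res.scale), abs=1e-9)
        # explicit quadratic-form oracle for Q
        resid = h.beta_y - est.beta * h.beta_x
        q_oracle = resid @ np.linalg.solve(omega, resid)
        assert het.Q == pytest.approx(q_oracle, abs=1e-9)

    def test_singular_ld_repaired_with_warning(self):
        h = make_harmonized([0.1, 0.1, 0.2], [0.01] * 3, [0.02] * 3, [0.01] * 3)
        r = np.ones((3, 3))  # perfectly correlated: rank 1
        ld = LDMatrix(h.variant_ids, r)
        with pytest.warns(RuntimeWarning, match="clipped 2"):
            est, _ = ivw_correlated(MRInput(h, ld=ld))
        assert np.isfinite(est.beta) and est.se > 0


class TestEgger:
    def test_too_few_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.02] * 2, [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(MRInput(h))

    def test_collinear_exposure_effects(self):
        h = make_harmonized([0.1, 0.1, -0.1], [0.01] * 3, [0.02, 0.02, 0.01], [0.01] * 3)
        with pytest.raises(CollinearityError):
            egger(MRInput(h))  # |beta_x| constant after orientation recoding

    def test_perfect_line_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.01 + 0.2 * bx
        h = make_harmonized(bx, [0.01] * 4, by, [0.05, 0.04, 0.03, 0.02])
        est, het = egger(MRInput(h))
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.intercept == pytest.approx(0.01, abs=1e-12)
        assert het.Q == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_intercept_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        h = random_harmonized(rng, 20)
        h.beta_x = np.abs(h.beta_x)  # already oriented: oracle needs no recoding
        est, het = egger(MRInput(h), effects_model=FIXED)
        X = sm.add_constant(h.beta_x)
        res = sm.WLS(h.beta_y, X, weights=1.0 / h.se_y**2).fit()
        assert est.beta == pytest.approx(res.params[1], abs=1e-9)
        assert est.intercept == pytest.approx(res.params[0], abs=1e-9)
        assert est.se == pytest.approx(res.bse[1] / np.sqrt(res.scale), abs=1e-9)
        assert est.intercept_se == pytest.approx(res.bse[0] / np.sqrt(res.scale), abs=1e-9)
        assert het.Q == pytest.approx(res.ssr, abs=1e-9)

    def test_orientation_invariance_with_ld(self, rng):
        J = 6
        h = random_harmonized(rng, J)
        d = np.abs(np.subtract.outer(np.arange(J), np.arange(J)))
        ld = LDMatrix(h.variant_ids, 0.4**d)
        est1, _ = egger(MRInput(h, ld=ld), correlated=True)
        flip = np.array([1, -1, 1, -1, -1, 1], dtype=float)
        h2 = make_harmonized(flip * h.beta_x, h.se_x, flip * h.beta_y, h.se_y)
        ld2 = LDMatrix(h.variant_ids, (0.4**d) * np.outer(flip, flip))
        est2, _ = egger(MRInput(h2, ld=ld2), correlated=True)
        assert est2.beta == pytest.approx(est1.beta, abs=1e-10)
        assert est2.intercept == pytest.approx(est1.intercept, abs=1e-10)


class TestMVMR:
    def test_k1_equals_ivw(self, rng):
        h = random_harmonized(rng, 9)
        est_mv, het_mv = mvmr_ivw(MRInput(h, exposure_matrix=h.beta_x[:, None]))
        est_uv, het_uv = ivw(MRInput(h))
        assert est_mv[0].beta == pytest.approx(est_uv.beta, abs=1e-12)
        assert est_mv[0].se == pytest.approx(est_uv.se, abs=1e-12)
        assert het_mv.Q == pytest.approx(het_uv.Q, abs=1e-12)

    def test_block_diagonal_equals_per_block_ivw(self, rng):
        # each variant loads on exactly one exposure: joint fit decouples
        J = 8
        h = random_harmonized(rng, J)
        X = np.zeros((J, 2))
        X[:4, 0] = h.beta_x[:4]
        X[4:, 1] = h.beta_x[4:]
        ests, _ = mvmr_ivw(MRInput(h, exposure_matrix=X), effects_model=FIXED)
        for k, sl in enumerate((slice(0, 4), slice(4, 8))):
            sub = make_harmonized(h.beta_x[sl], h.se_x[sl], h.beta_y[sl], h.se_y[sl])
            ref, _ = ivw(MRInput(sub), FIXED)
            assert ests[k].beta == pytest.approx(ref.beta, abs=1e-10)
            assert ests[k].se == pytest.approx(ref.se, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        J, K = 15, 3
        h = random_harmonized(rng, J)
        X = rng.normal(0, 0.1, (J, K))
        ests, het = mvmr_ivw(MRInput(h, exposure_matrix=X), effects_model=FIXED)
        res = sm.WLS(h.beta_y, X, weights=1.0 / h.se_y**2).fit()
        for k in range(K):
            assert ests[k].beta == pytest.approx(res.params[k], abs=1e-9)
            assert ests[k].se == pytest.approx(res.bse[k] / np.sqrt(res.scale), abs=1e-9)
        assert het.Q == pytest.approx(res.ssr, abs=1e-9)
        assert het.dof == J - K

    def test_j_not_greater_than_k_rejected(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.01] * 3, [0.02] * 3, [0.01] * 3)
        with pytest.raises(Exception) as err:
            MRInput(h, exposure_matrix=np.eye(3))
        assert "J > K" in str(err.value)

    def test_rank_deficiency_names_offenders(self, rng):
        J = 10
        h = random_harmonized(rng, J)
        col = rng.normal(0, 0.1, J)
        X = np.column_stack([col, 2 * col, rng.normal(0, 0.1, J)])
        with pytest.raises(CollinearityError, match="exposure_"):
            mvmr_ivw(MRInput(h, exposure_matrix=X))


@given(st.integers(0, 200))
def test_estimator_identity_suite(seed):
    """IVW(J=1)≡Wald, correlated-IVW(I)≡IVW, MVMR(K=1)≡IVW on random instances."""
    rng = np.random.default_rng(seed)
    J = int(rng.integers(3, 15))
    h = random_harmonized(rng, J)

    est_i, _ = ivw(MRInput(h))
    est_c, _ = ivw_correlated(MRInput(h, ld=identity_ld(J)))
    assert abs(est_c.beta - est_i.beta) < 1e-10
    assert abs(est_c.se - est_i.se) < 1e-10

    est_mv, _ = mvmr_ivw(MRInput(h, exposure_matrix=h.beta_x[:, None]))
    assert abs(est_mv[0].beta - est_i.beta) < 1e-10

    h1 = make_harmonized(h.beta_x[:1], h.se_x[:1], h.beta_y[:1], h.se_y[:1])
    est_w = wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0])
    est_1, _ = ivw(MRInput(h1))
    assert est_1.beta == est_w.beta and est_1.se == est_w.se
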