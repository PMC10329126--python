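"""Distributional correctness: closed forms, calculus identities, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.integrate import quad

from nbpvf import (
    NBPVFParams,
    RivalParams,
    bpt_cdf,
    bpt_pdf,
    nbpvf_cdf,
    nbpvf_chf,
    nbpvf_hf,
    nbpvf_pdf,
    nbpvf_quantile,
    nbpvf_rvs,
    nbpvf_sf,
    rival_cdf,
    rival_pdf,
    vfw_cdf,
    vfw_inner,
    vfw_pdf,
)
from conftest import TABLE_TRIPLES

W_GRID = np.array([0.2, 0.5, 1.0, 2.0, 5.0])


class TestInnerExponent:
    def test_closed_form_values(self):
        assert vfw_inner(1.0, 2.7, 0.4) == pytest.approx(0.4 - 1.0)
        assert vfw_inner(2.0, 1.0, 0.5) == pytest.approx(0.5)
        assert vfw_inner(0.5, 2.0, 1.3) == pytest.approx(-3.35)

    def test_strictly_increasing_with_infinite_limits(self):
        w = np.geomspace(1e-4, 1e3, 400)
        z = vfw_inner(w, 0.8, 1.1)
        assert np.all(np.diff(z) > 0)
        assert vfw_inner(1e-12, 0.8, 1.1) < -1e6
        assert vfw_inner(1e6, 0.8, 1.1) > 1e5

    def test_nonpositive_w_raises(self):
        with pytest.raises(ValueError):
            vfw_inner(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            vfw_inner(-1.0, 1.0, 1.0)


class TestBetaPowerTransform:
    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0, 7.3])
    def test_fixed_endpoints(self, beta):
        assert bpt_cdf(0.0, beta) == pytest.approx(0.0, abs=1e-15)
        assert bpt_cdf(1.0, beta) == pytest.approx(1.0, rel=1e-15)

    def test_hand_computed_values(self):
        assert bpt_cdf(0.5, 4.0) == pytest.approx(0.375)
        assert bpt_pdf(1.0, 0.0, np.e) == pytest.approx(2.0 / np.e)

    def test_identity_at_beta_one(self):
        G = np.linspace(0, 1, 11)
        assert bpt_cdf(G, 1.0) == pytest.approx(G, abs=1e-15)
        assert bpt_pdf(np.full_like(G, 0.7), G, 1.0) == pytest.approx(0.7)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        G=st.floats(0.0, 1.0),
        beta=st.floats(0.4, 20.0),
    )
    def test_monotone_and_bounded(self, G, beta):
        """The transform maps [0,1] into [0,1] monotonely for beta >= 1/e."""
        val = bpt_cdf(G, beta)
        assert -1e-12 <= val <= 1 + 1e-12
        assert bpt_cdf(min(G + 0.01, 1.0), beta) >= val - 1e-12

    def test_pdf_is_cdf_derivative_by_chain_rule(self):
        # compose with a smooth base CDF and check by central differences
        a, s, beta = 0.9, 1.1, 2.5
        w0 = 1.37  # G(w0) near 0.3 territory
        h = 1e-6
        num = (
            bpt_cdf(vfw_cdf(w0 + h, a, s), beta)
            - bpt_cdf(vfw_cdf(w0 - h, a, s), beta)
        ) / (2 * h)
        ana = bpt_pdf(vfw_pdf(w0, a, s), vfw_cdf(w0, a, s), beta)
        assert num == pytest.approx(ana, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bpt_cdf(1.5, 2.0)
        with pytest.raises(ValueError):
            bpt_pdf(-0.1, 0.5, 2.0)


class TestNBPVFFunctions:
    @pytest.mark.parametrize("params", TABLE_TRIPLES, ids=str)
    def test_pdf_integrates_to_one(self, params):
        total, err = quad(lambda w: nbpvf_pdf(w, params), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("params", TABLE_TRIPLES, ids=str)
    def test_cdf_matches_quadrature_of_pdf(self, params):
        val, _ = quad(lambda w: nbpvf_pdf(w, params), 0, 1.0, limit=200)
        assert nbpvf_cdf(1.0, params) == pytest.approx(val, abs=1e-8)

    def test_sf_matches_quadrature(self):
        params = NBPVFParams(1.1, 0.9, 1.3)
        val, _ = quad(lambda w: nbpvf_pdf(w, params), 0, 2.0, limit=200)
        assert nbpvf_sf(2.0, params) == pytest.approx(1.0 - val, abs=1e-7)

    @pytest.mark.parametrize("params", TABLE_TRIPLES, ids=str)
    def test_pdf_is_cdf_derivative(self, params):
        h = 1e-6
        for w in W_GRID:
            num = (nbpvf_cdf(w + h, params) - nbpvf_cdf(w - h, params)) / (2 * h)
            assert num == pytest.approx(nbpvf_pdf(w, params), rel=1e-6)

    @pytest.mark.parametrize("params", TABLE_TRIPLES, ids=str)
    def test_complement_hazard_and_cumulative_hazard_identities(self, params):
        F = nbpvf_cdf(W_GRID, params)
        S = nbpvf_sf(W_GRID, params)
        f = nbpvf_pdf(W_GRID, params)
        h = nbpvf_hf(W_GRID, params)
        H = nbpvf_chf(W_GRID, params)
        np.testing.assert_allclose(F + S, 1.0, atol=1e-12)
        # deep-tail points where F saturates to 1 in float64 are exactly
        # where the direct SF keeps accuracy that 1 - F cannot represent
        bulk = (F < 1.0) & (S > 0.0)
        np.testing.assert_allclose(h[bulk] * S[bulk], f[bulk], rtol=1e-10)
        np.testing.assert_allclose(H[bulk], -np.log1p(-F[bulk]), rtol=1e-10)
        assert np.all(np.diff(H) >= 0)

    def test_tail_behavior(self):
        params = NBPVFParams(1.0, 1.0, 1.2)
        assert nbpvf_cdf(1e-6, params) < 1e-12
        assert nbpvf_sf(1e-6, params) == pytest.approx(1.0, abs=1e-12)
        assert nbpvf_cdf(200.0, params) == 1.0

    def test_beta_one_reduces_to_vf_weibull(self):
        w = np.geomspace(0.05, 20, 80)
        for beta in (1.0, 1.0 + 1e-8, 1.0 - 1e-8):
            diff = np.abs(
                nbpvf_cdf(w, NBPVFParams(0.6, 1.3, beta)) - vfw_cdf(w, 0.6, 1.3)
            )
            assert diff.max() < 1e-6
        np.testing.assert_allclose(
            nbpvf_pdf(w, NBPVFParams(0.6, 1.3, 1.0)), vfw_pdf(w, 0.6, 1.3), rtol=1e-12
        )

    def test_cdf_is_bpt_of_base_cdf(self):
        """Transform-of-base composition: one shared code path."""
        a, s, beta = 0.7, 1.2, 1.4
        w = np.geomspace(0.1, 5, 40)
        composed = bpt_cdf(vfw_cdf(w, a, s), beta)
        np.testing.assert_array_equal(nbpvf_cdf(w, NBPVFParams(a, s, beta)), composed)

    def test_bathtub_hazard_shape_exists(self):
        # decreasing-then-increasing hazard for a small-alpha configuration
        params = NBPVFParams(0.3, 1.5, 0.45)
        w = np.linspace(0.05, 3.0, 400)
        h = nbpvf_hf(w, params)
        d = np.diff(h)
        sign_changes = np.flatnonzero(np.diff(np.sign(d)) != 0)
        assert d[0] < 0 and d[-1] > 0 and len(sign_changes) == 1

    def test_vectorized_support_convention(self):
        w = np.array([-1.0, 0.0, 1.0])
        F = nbpvf_cdf(w, TABLE_TRIPLES[0], strict=False)
        S = nbpvf_sf(w, TABLE_TRIPLES[0], strict=False)
        f = nbpvf_pdf(w, TABLE_TRIPLES[0], strict=False)
        assert F[0] == F[1] == 0.0 and S[0] == S[1] == 1.0 and f[0] == f[1] == 0.0
        with pytest.raises(ValueError):
            nbpvf_cdf(w, TABLE_TRIPLES[0])  # strict mode


class TestQuantileAndSampling:
    @pytest.mark.parametrize("params", TABLE_TRIPLES, ids=str)
    def test_round_trip(self, params):
        p = np.array([0.001, 0.01, 0.1, 0.5, 0.9, 0.99, 0.999])
        w = nbpvf_quantile(p, params)
        np.testing.assert_allclose(nbpvf_cdf(w, params), p, atol=1e-10)
        w0 = np.array([0.3, 0.8, 1.7])
        np.testing.assert_allclose(
            nbpvf_quantile(nbpvf_cdf(w0, params), params), w0, rtol=1e-8
        )

    def test_strictly_increasing(self):
        q = nbpvf_quantile(np.array([0.25, 0.5, 0.75]), TABLE_TRIPLES[1])
        assert q[0] < q[1] < q[2]

    def test_vf_weibull_limit_closed_form(self):
        # at beta=1 and p = 1 - e^(-1), the quantile solves z = 0, i.e.
        # sigma*w = w^(-alpha)  =>  w = sigma^(-1/(alpha+1))
        alpha, sigma = 0.8, 1.7
        p = -np.expm1(-1.0)
        w = nbpvf_quantile(p, NBPVFParams(alpha, sigma, 1.0))
        assert w == pytest.approx(sigma ** (-1.0 / (alpha + 1.0)), rel=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nbpvf_quantile(0.0, TABLE_TRIPLES[0])
        with pytest.raises(ValueError):
            nbpvf_quantile(1.0, TABLE_TRIPLES[0])
        with pytest.raises(ValueError):
            nbpvf_rvs(0, TABLE_TRIPLES[0])

    def test_sampler_reproducible_and_positive(self):
        a = nbpvf_rvs(100, TABLE_TRIPLES[0], seed=42)
        b = nbpvf_rvs(100, TABLE_TRIPLES[0], seed=42)
        np.testing.assert_array_equal(a, b)
        assert a.min() > 0

    def test_sampler_ks_consistency(self):
        w = nbpvf_rvs(5000, TABLE_TRIPLES[0], seed=42)
        stat = sps.kstest(w, lambda x: nbpvf_cdf(x, TABLE_TRIPLES[0])).statistic
        assert stat < 1.628 / np.sqrt(5000)  # 1% critical value


class TestRivalFamilies:
    def test_weibull_unit_exponential_point(self):
        assert rival_cdf(1.0, RivalParams("weibull", 1.0, 1.0)) == pytest.approx(
            -np.expm1(-1.0)
        )

    def test_exponentiated_reductions_at_gamma_one(self):
        w = np.geomspace(0.1, 5, 30)
        np.testing.assert_allclose(
            rival_cdf(w, RivalParams("e_weibull", 1.3, 0.7, 1.0)),
            rival_cdf(w, RivalParams("weibull", 1.3, 0.7)),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            rival_cdf(w, RivalParams("ef_weibull", 0.6, 1.1, 1.0)),
            rival_cdf(w, RivalParams("f_weibull", 0.6, 1.1)),
            rtol=1e-12,
        )

    @pytest.mark.parametrize(
        "params",
        [
            RivalParams("weibull", 1.4, 0.8),
            RivalParams("f_weibull", 0.9, 1.1),
            RivalParams("e_weibull", 1.2, 0.7, 2.3),
            RivalParams("ef_weibull", 0.8, 1.2, 1.6),
        ],
        ids=lambda p: p.family,
    )
    def test_pdf_normalizes_and_differentiates_cdf(self, params):
        total, _ = quad(lambda w: rival_pdf(w, params), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)
        h = 1e-6
        for w in W_GRID:
            num = (rival_cdf(w + h, params) - rival_cdf(w - h, params)) / (2 * h)
            assert num == pytest.approx(rival_pdf(w, params), rel=1e-6)

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            rival_cdf(1.0, RivalParams("gompertz", 1.0, 1.0))

    def test_gamma_requirements(self):
        with pytest.raises(ValueError):
            RivalParams("e_weibull", 1.0, 1.0).validate()
        with pytest.raises(ValueError):
            RivalParams("weibull", 1.0, 1.0, 2.0).validate()
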