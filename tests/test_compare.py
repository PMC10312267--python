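"""Bayesian data-comparison indices, model space and evidence labelling."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from specdcm.compare import (
    SWITCHED_OFF_VARIANCE,
    ModelSpace,
    bayesian_model_reduction,
    build_model_space,
    compare_datasets,
    information_gain_models,
    information_gain_parameters,
    label_evidence,
    parameter_certainty,
)
from specdcm.group import PebModel
from specdcm.model import DcmParameterLayout


def make_peb(beta_mean, beta_cov, prior_mean=None, prior_cov=None, n_regions=5):
    layout = DcmParameterLayout(n_regions)
    p = layout.n_off + n_regions
    beta_mean = np.asarray(beta_mean, dtype=float)
    assert beta_mean.size == p
    prior_mean = np.zeros(p) if prior_mean is None else prior_mean
    if prior_cov is None:
        prior_cov = np.diag(
            np.concatenate([np.full(layout.n_off, 1 / 64), np.full(n_regions, 1 / 256)])
        )
    return PebModel(
        design_matrix=np.ones((8, 1)),
        beta_mean=beta_mean,
        beta_covariance=np.asarray(beta_cov, dtype=float),
        between_subject_covariance=prior_cov / 16,
        free_energy=-100.0,
        prior_mean=prior_mean,
        prior_covariance=prior_cov,
        gamma=0.0,
        param_names=tuple(np.asarray(layout.names())[layout.a_indices]),
        n_regions=n_regions,
        connection_index={pair: k for k, pair in enumerate(layout.off_diagonal_pairs)},
    )


class TestParameterCertainty:
    def test_unit_determinant_scalar(self):
        assert parameter_certainty([[1.0 / (2 * np.pi * np.e)]]) == pytest.approx(0.0)

    def test_diagonal_factorizes(self):
        variances = np.array([0.5, 2.0, 0.01])
        total = parameter_certainty(np.diag(variances))
        parts = sum(parameter_certainty([[v]]) for v in variances)
        assert total == pytest.approx(parts, abs=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 5))
        cov = a @ a.T + np.eye(5)
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        assert parameter_certainty(q @ cov @ q.T) == pytest.approx(
            parameter_certainty(cov), abs=1e-9
        )

    def test_non_psd_rejected_with_eigenvalue(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            parameter_certainty(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_shrinking_covariance_increases_certainty(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 4))
        cov = a @ a.T + np.eye(4)
        assert parameter_certainty(0.5 * cov) > parameter_certainty(cov)


class TestInformationGainParameters:
    def test_identical_beliefs_give_zero(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        mean = np.array([0.5, -0.2])
        assert information_gain_parameters(mean, cov, mean, cov) == pytest.approx(0.0)

    def test_unit_shift_scalar(self):
        assert information_gain_parameters([0.0], [[1.0]], [1.0], [[1.0]]) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadrature_2d(self, seed):
        """Closed-form Gaussian KL against brute-force 2-D integration of
        q ln(q/p)."""
        rng = np.random.default_rng(seed)
        mu_p = rng.normal(0, 1, 2)
        mu_q = mu_p + rng.normal(0, 0.5, 2)
        a = rng.normal(0, 1, (2, 2))
        cov_p = a @ a.T + np.eye(2)
        b = rng.normal(0, 1, (2, 2))
        cov_q = b @ b.T + np.eye(2)
        closed = information_gain_parameters(mu_p, cov_p, mu_q, cov_q)
        q = stats.multivariate_normal(mu_q, cov_q)
        p = stats.multivariate_normal(mu_p, cov_p)
        sd = np.sqrt(np.diag(cov_q))
        lo, hi = mu_q - 8 * sd, mu_q + 8 * sd
        val, _ = integrate.dblquad(
            lambda y, x: q.pdf([x, y]) * (q.logpdf([x, y]) - p.logpdf([x, y])),
            lo[0],
            hi[0],
            lambda x: lo[1],
            lambda x: hi[1],
            epsabs=1e-9,
        )
        assert closed == pytest.approx(val, abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            information_gain_parameters([0.0], [[1.0]], [0.0, 0.0], np.eye(2))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegative_and_zero_iff_equal(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 4)
        mu_p, mu_q = rng.normal(0, 1, k), rng.normal(0, 1, k)
        a, b = rng.normal(0, 1, (k, k)), rng.normal(0, 1, (k, k))
        cov_p = a @ a.T + 0.1 * np.eye(k)
        cov_q = b @ b.T + 0.1 * np.eye(k)
        kl = information_gain_parameters(mu_p, cov_p, mu_q, cov_q)
        assert kl >= 0.0
        if kl == 0.0:
            np.testing.assert_allclose(mu_p, mu_q)
            np.testing.assert_allclose(cov_p, cov_q)


class TestModelSpace:
    def test_five_regions_leave_one_out_has_21_models(self):
        space = build_model_space(5)
        assert space.n_models == 21

    def test_two_regions_has_three_models(self):
        assert build_model_space(2).n_models == 3

    def test_uniform_prior_probabilities(self):
        space = build_model_space(5)
        np.testing.assert_allclose(space.prior_model_probabilities, 1.0 / 21.0)
        assert space.prior_model_probabilities.sum() == pytest.approx(1.0)

    def test_duplicate_masks_rejected(self):
        full = np.ones((2, 2), dtype=int)
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpace((full, full.copy()), np.array([0.5, 0.5]))

    def test_mask_zeroing_self_connection_rejected(self):
        full = np.ones((2, 2), dtype=int)
        bad = full.copy()
        bad[0, 0] = 0
        with pytest.raises(ValueError, match="self-connections"):
            ModelSpace((full, bad), np.array([0.5, 0.5]))


class TestBayesianModelReduction:
    def test_no_reduction_changes_nothing(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((3, 3))
        prior_cov = a @ a.T + np.eye(3)
        post_cov = 0.2 * prior_cov
        mu0, mu = np.zeros(3), rng.normal(0, 0.5, 3)
        mu_r, cov_r, delta = bayesian_model_reduction(
            mu, post_cov, mu0, prior_cov, mu0, prior_cov
        )
        assert delta == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(mu_r, mu, atol=1e-9)
        np.testing.assert_allclose(cov_r, post_cov, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_conjugate_gaussian_oracle(self, seed):
        """1-D conjugate model: the analytic evidence change equals a direct
        recomputation of the marginal likelihood under the reduced prior."""
        rng = np.random.default_rng(seed)
        m0, v0 = rng.normal(), np.exp(rng.normal())
        vy = np.exp(rng.normal(-1))
        y = rng.normal(m0, 1.0)
        v_post = 1.0 / (1.0 / v0 + 1.0 / vy)
        m_post = v_post * (m0 / v0 + y / vy)
        mr, vr = rng.normal(scale=0.5), np.exp(rng.normal(-1))

        def log_evidence(mean, var):
            return stats.norm.logpdf(y, mean, np.sqrt(var + vy))

        _, _, delta = bayesian_model_reduction(
            [m_post], [[v_post]], [m0], [[v0]], [mr], [[vr]]
        )
        assert delta == pytest.approx(log_evidence(mr, vr) - log_evidence(m0, v0), abs=1e-8)

    def test_switching_off_strong_connection_costs_more(self):
        """Removing a connection whose posterior sits 5 SD from zero loses
        more evidence than removing one centred at zero."""
        post_cov = np.eye(2) * 0.01
        prior_cov = np.eye(2) * (1 / 64)
        mu = np.array([0.5, 0.0])  # first entry 5 posterior SD from zero
        deltas = []
        for k in range(2):
            mr = mu.copy()
            covr = prior_cov.copy()
            mr[k] = 0.0
            covr[k, k] = SWITCHED_OFF_VARIANCE
            _, _, d = bayesian_model_reduction(
                mu, post_cov, np.zeros(2), prior_cov, mr * 0.0, covr
            )
            deltas.append(d)
        assert deltas[0] < deltas[1]


class TestInformationGainModels:
    def test_uninformed_posterior_gives_zero(self):
        """When the group belief equals its prior every reduced model has
        the same evidence and no information is gained."""
        layout = DcmParameterLayout(5)
        p = layout.n_off + 5
        prior_cov = np.diag(np.concatenate([np.full(20, 1 / 64), np.full(5, 1 / 256)]))
        peb = make_peb(np.zeros(p), prior_cov.copy(), prior_cov=prior_cov)
        space = build_model_space(5)
        assert information_gain_models(peb, space) == pytest.approx(0.0, abs=1e-9)

    def test_dominant_model_saturates_at_log_m(self):
        """All 20 connections strongly present: the full model dominates
        every reduction by far more than 30 nats, so the gain approaches
        ln 21."""
        p = 25
        beta = np.concatenate([np.full(20, 0.5), np.zeros(5)])
        peb = make_peb(beta, np.eye(p) * 1e-3)
        space = build_model_space(5)
        gain = information_gain_models(peb, space)
        assert gain == pytest.approx(np.log(21), abs=1e-6)

    def test_matches_direct_formula(self):
        """The discrete KL equals sum p ln(p M) evaluated from the same
        BMR evidence vector computed independently."""
        rng = np.random.default_rng(4)
        p = 25
        beta = np.concatenate([rng.normal(0, 0.15, 20), np.zeros(5)])
        peb = make_peb(beta, np.eye(p) * 2e-3)
        space = build_model_space(5)
        gain = information_gain_models(peb, space)

        from specdcm.compare import _mask_to_reduced_prior

        log_ev = []
        for mask in space.masks:
            mr, covr = _mask_to_reduced_prior(peb, mask)
            log_ev.append(
                bayesian_model_reduction(
                    peb.beta_mean,
                    peb.beta_covariance,
                    peb.prior_mean,
                    peb.prior_covariance,
                    mr,
                    covr,
                )[2]
            )
        log_ev = np.array(log_ev)
        w = np.exp(log_ev - log_ev.max())
        probs = w / w.sum()
        direct = float(np.sum(probs * np.log(probs * space.n_models)))
        assert gain == pytest.approx(direct, abs=1e-9)

    def test_bounded_by_log_m(self):
        rng = np.random.default_rng(5)
        p = 25
        beta = np.concatenate([rng.normal(0, 0.3, 20), np.zeros(5)])
        peb = make_peb(beta, np.eye(p) * 1e-3)
        space = build_model_space(5)
        gain = information_gain_models(peb, space)
        assert 0.0 <= gain <= np.log(space.n_models)


class TestLabelEvidence:
    @pytest.mark.parametrize(
        "delta,label",
        [
            (0.0, "insufficient"),
            (0.23, "insufficient"),
            (1.09, "insufficient"),
            (1.1, "positive"),
            (2.9, "positive"),
            (3.0, "strong"),
            (4.0, "strong"),
            (5.0, "very strong"),
            (10.5, "very strong"),
        ],
    )
    def test_bins(self, delta, label):
        assert label_evidence(delta) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            label_evidence(-0.1)


class TestCompareDatasets:
    def _peb_pair(self):
        rng = np.random.default_rng(6)
        beta_a = np.concatenate([rng.normal(0, 0.1, 20), np.zeros(5)])
        beta_b = np.concatenate([rng.normal(0, 0.25, 20), np.zeros(5)])
        return make_peb(beta_a, np.eye(25) * 2e-3), make_peb(beta_b, np.eye(25) * 3e-3)

    def test_self_comparison_is_null(self):
        peb, _ = self._peb_pair()
        report = compare_datasets(peb, peb, label_a="a", label_b="b")
        for name, delta in report.differences.items():
            assert delta == pytest.approx(0.0, abs=1e-12)
            assert report.evidence_labels[name] == "insufficient"

    def test_differences_nonnegative_and_labelled(self):
        peb_a, peb_b = self._peb_pair()
        report = compare_datasets(peb_a, peb_b, label_a="rest", label_b="task")
        for name, delta in report.differences.items():
            assert delta >= 0.0
            assert report.evidence_labels[name] == label_evidence(delta)
            assert report.best[name] in ("rest", "task")

    def test_order_invariance(self):
        peb_a, peb_b = self._peb_pair()
        fwd = compare_datasets(peb_a, peb_b, label_a="x", label_b="y")
        rev = compare_datasets(peb_b, peb_a, label_a="y", label_b="x")
        for name in fwd.differences:
            assert fwd.differences[name] == pytest.approx(rev.differences[name], abs=1e-12)
            assert fwd.best[name] == rev.best[name]

    def test_mismatched_parameterizations_rejected(self):
        peb_a, _ = self._peb_pair()
        layout3 = DcmParameterLayout(3)
        small = make_peb(
            np.zeros(layout3.n_off + 3),
            np.eye(layout3.n_off + 3) * 1e-3,
            prior_cov=np.eye(layout3.n_off + 3) * (1 / 64),
            n_regions=3,
        )
        with pytest.raises(ValueError, match="mismatched"):
            compare_datasets(peb_a, small)

    def test_sharper_shifted_posterior_scores_higher(self):
        """Scaling the covariance down (means fixed away from the prior)
        strictly increases certainty and parameter gain."""
        rng = np.random.default_rng(7)
        beta = np.concatenate([rng.normal(0, 0.2, 20), np.zeros(5)])
        cov = np.eye(25) * 2e-3
        loose = make_peb(beta, cov)
        tight = make_peb(beta, 0.5 * cov)
        space = build_model_space(5)
        report = compare_datasets(loose, tight, space, "loose", "tight")
        assert report.best["parameter_certainty"] == "tight"
        assert report.best["info_gain_parameters"] == "tight"
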