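"""Mixture-likelihood pieces against independent oracles, and fit equivalences."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import norm

from trajgroup.gbtm import (
    GbtmParams,
    TrajectoryModelSpec,
    bernoulli_logit_loglik,
    censored_mean,
    censored_normal_loglik,
    fit,
    membership_probs,
    mixture_loglik,
    subject_group_loglik,
    trajectory_mean,
)
from trajgroup.synthetic_data import simulate_panel
from tests.conftest import make_panel, recovery_design


def brute_force_subject_probs(panel, params, spec):
    """Enumeration oracle: P(Y_i) = sum_j pi_j(x_i) prod_t P(y_it | j), plain loops."""
    out = {}
    for pid, grp in panel.groupby("patient_id", sort=True):
        x = np.array([1.0] + (
            [float(grp["etiology"].iloc[0] == "HNC")] if params.theta.shape[1] > 1 else []
        ))
        pi = membership_probs(params.theta, x)
        terms = []
        for j, beta in enumerate(params.beta):
            prob = 1.0
            for _, row in grp.iterrows():
                eta = sum(b * row["trial"] ** p for p, b in enumerate(beta))
                if spec.link == "logit":
                    p1 = expit(eta)
                    prob *= p1 if row["score"] == 1 else 1 - p1
                else:
                    prob *= math.exp(
                        censored_normal_loglik(row["score"], eta, params.sigma, spec.bounds)
                    )
            terms.append(pi[j] * prob)
        out[pid] = terms
    return out


class TestTrajectoryMean:
    def test_polynomial_values(self):
        assert trajectory_mean((0, 0, 0, 0), 5) == 0.0
        assert trajectory_mean((1, 0, 0, 0), 7) == 1.0
        assert trajectory_mean((0, 1, -0.1, 0), 3) == pytest.approx(2.1)

    def test_overlong_coefficients_rejected(self):
        with pytest.raises(ValueError, match="cubic"):
            trajectory_mean((1, 1, 1, 1, 1), 2)


class TestCensoredNormal:
    def test_boundary_closed_forms(self):
        assert censored_normal_loglik(0.0, 0.0, 1.0, (0, 4)) == pytest.approx(np.log(0.5))
        assert censored_normal_loglik(2.0, 2.0, 1.0, (0, 4)) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )
        # upper bound: tail probability from the normal-CDF oracle
        assert censored_normal_loglik(4.0, 2.0, 1.0, (0, 4)) == pytest.approx(
            np.log(1 - norm.cdf(2.0)), abs=1e-12
        )

    def test_error_conditions(self):
        with pytest.raises(ValueError, match="sigma"):
            censored_normal_loglik(1.0, 0.0, -1.0, (0, 4))
        with pytest.raises(ValueError, match="bounds"):
            censored_normal_loglik(5.0, 0.0, 1.0, (0, 4))

    def test_censored_mean_stays_in_bounds(self):
        mu = np.linspace(-10, 10, 41)
        m = censored_mean(mu, 1.5, (0, 4))
        assert np.all(m >= 0) and np.all(m <= 4)
        # far-interior mean is essentially uncensored
        assert censored_mean(2.0, 0.1, (0, 4)) == pytest.approx(2.0, abs=1e-10)


class TestSubjectGroupLoglik:
    def test_flat_logit_and_additivity(self):
        assert subject_group_loglik([1], [1], (0.0,), "logit") == pytest.approx(np.log(0.5))
        two = subject_group_loglik([1, 2], [1, 0], (0.0,), "logit")
        assert two == pytest.approx(2 * np.log(0.5))

    def test_equals_brute_force_product(self):
        rng = np.random.default_rng(5)
        trials = np.arange(1, 8)
        scores = rng.integers(0, 2, size=7)
        beta = (-0.5, 0.3, -0.04, 0.001)
        ll = subject_group_loglik(trials, scores, beta, "logit")
        brute = sum(
            np.log(expit(trajectory_mean(beta, t)) if s == 1 else 1 - expit(trajectory_mean(beta, t)))
            for t, s in zip(trials, scores)
        )
        assert ll == pytest.approx(brute, abs=1e-12)

    def test_empty_subject_rejected(self):
        with pytest.raises(ValueError, match="no observed trials"):
            subject_group_loglik([], [], (0.0,), "logit")


class TestMembershipProbs:
    def test_uniform_and_direct_arithmetic(self):
        np.testing.assert_allclose(membership_probs(np.zeros((3, 1))), np.full(3, 1 / 3))
        pi = membership_probs(np.array([[0.0], [np.log(3.0)]]))
        np.testing.assert_allclose(pi, [0.25, 0.75], atol=1e-12)

    def test_nonzero_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            membership_probs(np.array([[0.5], [0.0]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8))
    def test_sums_to_one(self, logits):
        theta = np.array([[0.0]] + [[v] for v in logits])
        assert membership_probs(theta).sum() == pytest.approx(1.0, abs=1e-12)


class TestMixtureLoglik:
    def test_matches_enumeration_on_tiny_instance(self, tiny_panel):
        spec = TrajectoryModelSpec(k=2, poly_orders=(1, 1), link="logit")
        params = GbtmParams(
            beta=(np.array([-1.0, 0.3]), np.array([0.8, -0.2])),
            theta=np.array([[0.0], [0.4]]),
        )
        ll = mixture_loglik(tiny_panel, params, spec)
        brute = brute_force_subject_probs(tiny_panel, params, spec)
        expected = sum(np.log(sum(v)) for v in brute.values())
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_k1_reduces_to_single_group(self, tiny_panel):
        spec = TrajectoryModelSpec(k=1, poly_orders=(2,), link="logit")
        beta = np.array([0.5, -0.3, 0.02])
        params = GbtmParams(beta=(beta,), theta=np.zeros((1, 1)))
        ll = mixture_loglik(tiny_panel, params, spec)
        direct = sum(
            subject_group_loglik(g["trial"], g["score"], beta, "logit")
            for _, g in tiny_panel.groupby("patient_id")
        )
        assert ll == pytest.approx(direct, abs=1e-12)

    def test_duplicating_subjects_doubles_loglik(self, tiny_panel):
        spec = TrajectoryModelSpec(k=2, poly_orders=(0, 0), link="logit")
        params = GbtmParams(beta=(np.array([-1.0]), np.array([1.0])), theta=np.array([[0.0], [0.2]]))
        doubled = pd.concat(
            [tiny_panel, tiny_panel.assign(patient_id=tiny_panel["patient_id"] + "_copy")]
        )
        assert mixture_loglik(doubled, params, spec) == pytest.approx(
            2 * mixture_loglik(tiny_panel, params, spec), abs=1e-10
        )

    def test_label_permutation_invariance(self, tiny_panel):
        spec = TrajectoryModelSpec(k=3, poly_orders=(1, 1, 1), link="logit")
        betas = (np.array([-1.0, 0.1]), np.array([0.0, 0.2]), np.array([1.0, -0.1]))
        theta = np.array([[0.0], [0.5], [-0.3]])
        ll = mixture_loglik(tiny_panel, GbtmParams(beta=betas, theta=theta), spec)
        perm = [2, 0, 1]
        theta_p = theta[perm] - theta[perm[0]]
        ll_p = mixture_loglik(
            tiny_panel, GbtmParams(beta=tuple(betas[j] for j in perm), theta=theta_p), spec
        )
        assert ll_p == pytest.approx(ll, abs=1e-10)


class TestFitDegenerate:
    def test_k1_intercept_only_closed_form(self, recovery_panel):
        panel, _ = recovery_panel
        model = fit(panel, TrajectoryModelSpec(k=1, poly_orders=0, link="logit", seed=0, gtol=1e-12, ftol=1e-15))
        p_hat = panel["score"].mean()
        assert model.beta[0][0] == pytest.approx(np.log(p_hat / (1 - p_hat)), abs=1e-6)

    def test_k1_cubic_matches_glm(self):
        from trajgroup.synthetic_data import GroupTruth, SimulationDesign

        design = SimulationDesign(
            n_subjects=300,
            etiology_probs=(0.3, 0.4, 0.3),
            groups=(GroupTruth("g", (-1.5, 0.9, -0.12, 0.005)),),
            membership_coeffs=np.zeros((1, 3)),
            seed=9,
        )
        panel, _ = simulate_panel(design)
        model = fit(panel, TrajectoryModelSpec(k=1, poly_orders=3, link="logit", seed=0, gtol=1e-12, ftol=1e-15))
        t = panel["trial"].to_numpy(float)
        X = np.vander(t, 4, increasing=True)
        glm = sm.GLM(panel["score"].to_numpy(), X, family=sm.families.Binomial()).fit(tol=1e-12)
        np.testing.assert_allclose(model.beta[0], glm.params, rtol=1e-5)

    def test_cnorm_nonbinding_bounds_matches_ols(self):
        rng = np.random.default_rng(4)
        n = 200
        t = np.tile(np.arange(1, 8), n)
        panel = pd.DataFrame(
            {
                "patient_id": np.repeat([f"P{i:03d}" for i in range(n)], 7),
                "etiology": "PD",
                "trial": t,
                "consistency": "thin",
                "variable": "piecemeal_deglutition",
                "score": rng.normal(2.0 + 0.15 * t, 0.7),
            }
        )
        model = fit(
            panel,
            TrajectoryModelSpec(k=1, poly_orders=1, link="cnorm", bounds=(-50, 50), seed=0, gtol=1e-12, ftol=1e-15),
        )
        X = np.vander(t, 2, increasing=True)
        b_ols = np.linalg.lstsq(X, panel["score"], rcond=None)[0]
        sigma_ml = np.sqrt(np.mean((panel["score"] - X @ b_ols) ** 2))
        np.testing.assert_allclose(model.beta[0], b_ols, rtol=1e-5)
        assert model.sigma == pytest.approx(sigma_ml, rel=1e-5)


class TestFitStructure:
    def test_multi_start_monotone_and_bic_identity(self, recovery_panel):
        panel, _ = recovery_panel
        model = fit(panel, TrajectoryModelSpec(k=3, poly_orders=0, link="logit", n_starts=3, seed=0))
        best = max(rec["loglik"] for rec in model.start_log)
        assert model.loglik >= best - 1e-9
        n = panel["patient_id"].nunique()
        assert model.bic == pytest.approx(-2 * model.loglik + model.n_params * np.log(n))
        assert np.all(model.theta[0] == 0.0)
        # canonical order: ascending impairment
        intercepts = [b[0] for b in model.beta]
        assert intercepts == sorted(intercepts)

    def test_same_seed_reproducible(self, recovery_panel):
        panel, _ = recovery_panel
        spec = TrajectoryModelSpec(k=2, poly_orders=0, link="logit", n_starts=2, seed=3)
        m1, m2 = fit(panel, spec), fit(panel, spec)
        assert m1.loglik == m2.loglik
        for b1, b2 in zip(m1.beta, m2.beta):
            np.testing.assert_array_equal(b1, b2)

    def test_undichotomized_logit_panel_rejected(self):
        panel = make_panel([("A", "PD", 1, 2), ("A", "PD", 2, 0)])
        with pytest.raises(ValueError, match="dichotomize"):
            fit(panel, TrajectoryModelSpec(k=1, poly_orders=0, link="logit"))

    def test_spec_guards(self):
        with pytest.raises(ValueError, match="k must be"):
            TrajectoryModelSpec(k=6)
        with pytest.raises(ValueError, match="orders"):
            TrajectoryModelSpec(k=2, poly_orders=(4, 0))


class TestParameterRecovery:
    def test_recovers_mixing_intercepts_and_classification(self, recovery_panel):
        """Well-separated 3-group simulation: proportions, intercepts, accuracy."""
        from trajgroup.posterior import posterior_probs

        panel, truth = recovery_panel
        model = fit(panel, TrajectoryModelSpec(k=3, poly_orders=0, link="logit", n_starts=3, seed=0))
        pi = membership_probs(model.theta)
        np.testing.assert_allclose(pi, [0.5, 0.3, 0.2], atol=0.05)
        intercepts = np.array([b[0] for b in model.beta])
        np.testing.assert_allclose(intercepts, [-3.0, 0.0, 3.0], atol=0.4)
        post = posterior_probs(panel, model)
        accuracy = (post.subjects["modal"].to_numpy() - 1 == truth.true_group.to_numpy()).mean()
        assert accuracy >= 0.90
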