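"""Tests of the cumulative-Gaussian maximum-likelihood fitter and bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, norm
from sklearn.base import clone

from tiltnorm.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    NonIdentifiableError,
)
from tiltnorm.observer import ObserverModel, SessionDesign, build_session, \
    simulate_responses
from tiltnorm.psychometric import (
    CumulativeGaussianPsychometric,
    deviance,
    fit_ml,
    negative_log_likelihood,
    parametric_bootstrap,
    psychometric_probability,
)

from conftest import binned

LEVELS = np.array([-4.0, -2.4, -0.8, 0.8, 2.4, 4.0])


def simulate_binned(pse, sigma, lapse, n_per_level, seed, levels=LEVELS):
    rng = np.random.default_rng(seed)
    p = psychometric_probability(levels, pse, sigma, lapse)
    n = np.full(levels.size, n_per_level, dtype=float)
    k = rng.binomial(n_per_level, p).astype(float)
    return levels, n, k


class TestProbability:
    def test_half_at_pse(self):
        assert psychometric_probability(1.3, 1.3, 2.0, 0.0) == pytest.approx(0.5)

    def test_asymptotes_set_by_lapse(self):
        assert psychometric_probability(1e9, 0.0, 2.0, 0.04) == pytest.approx(0.98)
        assert psychometric_probability(-1e9, 0.0, 2.0, 0.04) == pytest.approx(0.02)

    def test_phi_one(self):
        assert psychometric_probability(2.0, 0.0, 2.0, 0.0) == pytest.approx(
            norm.cdf(1.0), abs=1e-6
        )

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            psychometric_probability(0.0, 0.0, -1.0)
        with pytest.raises(InvalidParameterError):
            psychometric_probability(0.0, 0.0, 1.0, lapse=0.7)

    @settings(max_examples=50, deadline=None)
    @given(
        pse=st.floats(-4, 4),
        sigma=st.floats(0.1, 10),
        lapse=st.floats(0, 0.49),
    )
    def test_monotone_and_bounded(self, pse, sigma, lapse):
        theta = np.linspace(-20, 20, 101)
        p = psychometric_probability(theta, pse, sigma, lapse)
        assert np.all(np.diff(p) >= 0)
        assert np.all(p >= lapse / 2 - 1e-12)
        assert np.all(p <= 1 - lapse / 2 + 1e-12)


class TestNegativeLogLikelihood:
    def test_hand_computed_value(self):
        # one level, n = 2, k = 1, p = 0.5 -> -2 ln(1/2)
        nll = negative_log_likelihood((0.0, 1.0, 0.0), [0.0], [2.0], [1.0])
        assert nll == pytest.approx(-2.0 * np.log(0.5), abs=1e-9)

    def test_perfect_prediction_is_zero(self):
        # saturated cell: p -> 1 with k = n, clamped only by epsilon
        nll = negative_log_likelihood((-1e6, 1.0, 0.0), [0.0], [5.0], [5.0])
        assert nll == pytest.approx(0.0, abs=1e-6)

    def test_generating_params_beat_distorted_params(self):
        levels, n, k = simulate_binned(0.5, 2.0, 0.02, 200, seed=4)
        good = negative_log_likelihood((0.5, 2.0, 0.02), levels, n, k)
        bad = negative_log_likelihood((3.5, 6.0, 0.02), levels, n, k)
        assert good < bad

    def test_empty_data_rejected(self):
        with pytest.raises(InvalidInputError):
            negative_log_likelihood((0, 1, 0), [], [], [])


class TestFitML:
    def test_parameter_recovery_at_session_size(self):
        """PSE recovered within 0.3 deg from 1,200 trials (200 per level)."""
        levels, n, k = simulate_binned(1.5, 2.0, 0.02, 200, seed=11)
        fit = fit_ml(levels, n, k)
        assert fit.converged
        assert fit.pse == pytest.approx(1.5, abs=0.3)

    def test_self_consistency_on_exact_proportions(self):
        """Noiseless expected counts recover the generating parameters."""
        p = psychometric_probability(LEVELS, 0.8, 2.5, 0.02)
        n = np.full(LEVELS.size, 10_000.0)
        fit = fit_ml(LEVELS, n, n * p)
        assert fit.pse == pytest.approx(0.8, abs=0.02)
        assert fit.sigma == pytest.approx(2.5, rel=0.02)
        assert fit.lapse == pytest.approx(0.02, abs=0.005)

    def test_step_data_gives_finite_pse_between_levels(self):
        """All-or-nothing responses split at a boundary: steep, converged fit
        with the PSE inside the straddled gap (checked against a profile scan)."""
        n = np.full(LEVELS.size, 50.0)
        k = np.where(LEVELS > 0, 50.0, 0.0)
        fit = fit_ml(LEVELS, n, k, fit_lapse=False)
        assert fit.converged
        assert -0.8 <= fit.pse <= 0.8
        assert fit.sigma < 0.5  # steep
        # profile scan over pse at the fitted sigma: the likelihood valley is
        # flat across the straddled gap, and the fit must sit at its floor
        grid = np.linspace(-2.0, 2.0, 401)
        nll = [
            negative_log_likelihood((g, fit.sigma, 0.0), LEVELS, n, k) for g in grid
        ]
        at_fit = negative_log_likelihood((fit.pse, fit.sigma, 0.0), LEVELS, n, k)
        assert at_fit <= min(nll) + 1e-6

    def test_constant_responses_not_identifiable(self):
        n = np.full(LEVELS.size, 50.0)
        with pytest.raises(NonIdentifiableError):
            fit_ml(LEVELS, n, np.zeros(LEVELS.size))
        with pytest.raises(NonIdentifiableError):
            fit_ml(LEVELS, n, n.copy())

    def test_needs_three_levels(self):
        with pytest.raises(InvalidInputError):
            fit_ml([-1.0, 1.0], [50, 50], [10, 40])

    def test_matches_brute_force_grid_search(self):
        """Oracle equivalence: exhaustive (pse, sigma) grid search with the
        full binomial likelihood agrees with the optimizer on small data."""
        for seed in (1, 2, 3):
            levels, n, k = simulate_binned(0.7, 2.2, 0.0, 40, seed=seed)
            fit = fit_ml(levels, n, k, fit_lapse=False)
            pse_grid = np.linspace(-4, 4, 161)  # 0.05 deg resolution
            sig_grid = np.geomspace(0.3, 12, 120)
            best, best_ll = None, -np.inf
            for p0 in pse_grid:
                pr = norm.cdf((levels[None, :] - p0) / sig_grid[:, None])
                pr = np.clip(pr, 1e-9, 1 - 1e-9)
                ll = binom.logpmf(k[None, :], n[None, :], pr).sum(axis=1)
                i = int(np.argmax(ll))
                if ll[i] > best_ll:
                    best_ll, best = ll[i], (p0, sig_grid[i])
            assert fit.pse == pytest.approx(best[0], abs=0.06)
            assert fit.sigma == pytest.approx(best[1], rel=0.05)

    def test_slope_halves_when_sigma_doubles(self):
        """Reparameterization sanity for the derivative-at-PSE slope measure."""
        p1 = psychometric_probability(LEVELS, 0.0, 1.5, 0.0)
        p2 = psychometric_probability(LEVELS, 0.0, 3.0, 0.0)
        n = np.full(LEVELS.size, 20_000.0)
        f1 = fit_ml(LEVELS, n, n * p1, fit_lapse=False)
        f2 = fit_ml(LEVELS, n, n * p2, fit_lapse=False)
        assert f2.slope == pytest.approx(f1.slope / 2, rel=0.02)


class TestDeviance:
    def test_zero_when_fit_equals_saturated(self):
        p = psychometric_probability(LEVELS, 0.0, 2.0, 0.0)
        n = np.full(LEVELS.size, 100.0)
        fit = fit_ml(LEVELS, n, n * p, fit_lapse=False)
        assert deviance(fit, LEVELS, n, n * p) == pytest.approx(0.0, abs=1e-3)

    def test_nonnegative_on_random_data(self):
        for seed in range(5):
            levels, n, k = simulate_binned(0.0, 2.0, 0.02, 60, seed=seed)
            fit = fit_ml(levels, n, k)
            assert fit.deviance >= 0.0

    def test_mean_deviance_matches_chi_square_df(self):
        """Well-specified data: mean deviance ~ levels - params = 3 over
        200 replicates (chi-square calibration)."""
        devs = []
        for seed in range(200):
            levels, n, k = simulate_binned(0.5, 2.0, 0.0, 200, seed=1000 + seed)
            devs.append(fit_ml(levels, n, k, fit_lapse=False).deviance)
        assert 1.0 <= np.mean(devs) <= 6.0


@pytest.fixture(scope="module")
def fitted():
    levels, n, k = simulate_binned(1.0, 2.0, 0.02, 200, seed=21)
    return fit_ml(levels, n, k), levels, n, k


class TestParametricBootstrap:

    def test_default_sample_count_is_10000(self):
        import inspect

        sig = inspect.signature(parametric_bootstrap)
        assert sig.parameters["n_samples"].default == 10_000

    def test_point_estimate_inside_its_ci(self, fitted):
        fit, levels, n, k = fitted
        boot = parametric_bootstrap(fit, levels, n, k, n_samples=300, seed=5)
        lo, hi = boot.ci["pse"]
        assert lo <= fit.pse <= hi
        assert boot.n_failed <= 0.2 * 300

    def test_deterministic_given_seed(self, fitted):
        fit, levels, n, k = fitted
        a = parametric_bootstrap(fit, levels, n, k, n_samples=100, seed=9)
        b = parametric_bootstrap(fit, levels, n, k, n_samples=100, seed=9)
        assert a.ci == b.ci

    def test_ci_narrows_with_more_trials(self):
        """Quadrupling the trial count shrinks the PSE interval."""
        widths = {}
        for n_per, seed in ((50, 31), (200, 31)):
            levels, n, k = simulate_binned(1.0, 2.0, 0.02, n_per, seed=seed)
            fit = fit_ml(levels, n, k)
            boot = parametric_bootstrap(fit, levels, n, k, n_samples=300, seed=7)
            widths[n_per] = boot.ci["pse"][1] - boot.ci["pse"][0]
        assert widths[200] < widths[50]


class TestEstimator:
    def test_fit_predict_roundtrip(self, simulated_session):
        sub = simulated_session[simulated_session["condition"] == "single"]
        X = sub[["varied_orientation_deg"]].to_numpy()
        y = sub["response_chose_varied"].to_numpy()
        est = CumulativeGaussianPsychometric().fit(X, y)
        assert est.converged_
        assert est.pse_ == pytest.approx(-1.5, abs=0.5)
        proba = est.predict_proba(np.array([[est.pse_]]))
        assert proba.shape == (1, 2)
        assert proba[0, 1] == pytest.approx(0.5, abs=0.03)
        assert set(est.predict(X)) <= {0, 1}

    def test_sklearn_param_interface(self):
        est = CumulativeGaussianPsychometric(lapse_max=0.1)
        assert est.get_params()["lapse_max"] == 0.1
        cloned = clone(est).set_params(fit_lapse=False)
        assert cloned.get_params()["fit_lapse"] is False

    def test_agrees_with_binned_fit(self, simulated_session):
        sub = simulated_session[simulated_session["condition"] == "compound"]
        est = CumulativeGaussianPsychometric().fit(
            sub[["varied_orientation_deg"]].to_numpy(),
            sub["response_chose_varied"].to_numpy(),
        )
        levels, n, k = binned(simulated_session, "compound")
        fit = fit_ml(levels, n, k)
        assert est.pse_ == pytest.approx(fit.pse, abs=1e-9)
        assert est.nll_ == pytest.approx(fit.nll, abs=1e-9)
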