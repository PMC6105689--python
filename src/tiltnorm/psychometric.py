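"""Maximum-likelihood cumulative-Gaussian psychometric fitting.

The response model is

    psi(theta) = lapse/2 + (1 - lapse) * Phi((theta - pse) / sigma)

with ``pse`` the 50% point (point of subjective equality), ``sigma`` the
inverse slope and ``lapse`` the total stimulus-independent error rate,
split symmetrically between the asymptotes.  Fitting maximizes the binomial
likelihood of binned (level, n, k) data; goodness of fit is reported as the
deviance against the saturated model, and confidence intervals come from a
parametric Monte-Carlo bootstrap (simulate from the fitted curve, refit,
take percentile intervals).

The estimator `CumulativeGaussianPsychometric` follows scikit-learn
conventions (``fit``/``predict_proba``/``get_params``); the module-level
functions `fit_ml`, `deviance` and `parametric_bootstrap` are thin wrappers
usable without the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr, xlogy
from sklearn.base import BaseEstimator

from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    NonIdentifiableError,
)

__all__ = [
    "PsychometricFit",
    "BootstrapResult",
    "psychometric_probability",
    "negative_log_likelihood",
    "fit_ml",
    "deviance",
    "parametric_bootstrap",
    "CumulativeGaussianPsychometric",
]

#: Likelihood clamping bound keeping log-probabilities finite on saturated cells.
DEFAULT_EPS = 1e-9
#: Default upper bound on the fitted lapse rate.
DEFAULT_LAPSE_MAX = 0.05
#: Default number of parametric-bootstrap samples.
DEFAULT_N_BOOTSTRAP = 10_000

_SIGMA_STARTS = (0.5, 1.0, 2.0, 4.0, 8.0)
_LAPSE_STARTS = (0.0, 0.02)
_SIGMA_BOUNDS = (1e-2, 1e2)


def psychometric_probability(theta, pse, sigma, lapse=0.0):
    """Choice probability of the cumulative-Gaussian psychometric function."""
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    if not 0.0 <= lapse < 0.5:
        raise InvalidParameterError("lapse must lie in [0, 0.5)")
    theta = np.asarray(theta, dtype=float)
    p = lapse / 2.0 + (1.0 - lapse) * ndtr((theta - pse) / sigma)
    return p if p.ndim else float(p)


def _check_binned(levels, n, k):
    levels = np.asarray(levels, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if levels.size == 0:
        raise InvalidInputError("binned data is empty")
    if levels.shape != n.shape or levels.shape != k.shape:
        raise InvalidInputError("levels, n and k must have equal length")
    if len(np.unique(levels)) != levels.size:
        raise InvalidInputError("orientation levels must be distinct")
    if np.any(n <= 0) or np.any(k < 0) or np.any(k > n):
        raise InvalidInputError("counts must satisfy 0 <= k <= n, n > 0")
    order = np.argsort(levels)
    return levels[order], n[order], k[order]


def _nll_raw(params, levels, n, k, eps):
    """NLL without input validation (hot path)."""
    pse, sigma, lapse = params
    if sigma <= 0 or not 0.0 <= lapse < 0.5:
        return np.inf
    p = lapse / 2.0 + (1.0 - lapse) * ndtr((levels - pse) / sigma)
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def negative_log_likelihood(params, levels, n, k, eps=DEFAULT_EPS):
    """Binomial negative log-likelihood of (pse, sigma, lapse) on binned data.

    Binomial coefficients are omitted (constant in the parameters);
    probabilities are clamped to [eps, 1 - eps].
    """
    levels, n, k = _check_binned(levels, n, k)
    pse, sigma, lapse = params
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    if not 0.0 <= lapse < 0.5:
        raise InvalidParameterError("lapse must lie in [0, 0.5)")
    return _nll_raw(params, levels, n, k, eps)


_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _nll_and_grad(x, levels, n, k, eps, fit_lapse):
    """NLL and its analytic gradient in (pse, sigma, lapse)."""
    pse, sigma, lapse = x
    z = (levels - pse) / sigma
    cdf = ndtr(z)
    phi = _INV_SQRT_2PI * np.exp(-0.5 * z * z)
    p_raw = lapse / 2.0 + (1.0 - lapse) * cdf
    p = np.clip(p_raw, eps, 1.0 - eps)
    nll = -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    # d(nll)/dp, zeroed where the clamp is active
    dldp = np.where(
        (p_raw > eps) & (p_raw < 1.0 - eps), -(k / p - (n - k) / (1.0 - p)), 0.0
    )
    dpdpse = -(1.0 - lapse) * phi / sigma
    dpdsigma = -(1.0 - lapse) * phi * z / sigma
    grad = np.array(
        [
            np.sum(dldp * dpdpse),
            np.sum(dldp * dpdsigma),
            np.sum(dldp * (0.5 - cdf)) if fit_lapse else 0.0,
        ]
    )
    return float(nll), grad


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood fit of one psychometric function."""

    pse: float
    sigma: float
    lapse: float
    nll: float
    deviance: float
    converged: bool
    n_levels: int = 0
    n_trials: int = 0

    @property
    def slope(self) -> float:
        """Derivative of the fitted curve at the PSE (per degree)."""
        return (1.0 - self.lapse) / (self.sigma * np.sqrt(2.0 * np.pi))

    def probability(self, theta):
        return psychometric_probability(theta, self.pse, self.sigma, self.lapse)


def _saturated_loglik(n, k):
    phat = k / n
    return float(np.sum(xlogy(k, phat) + xlogy(n - k, 1.0 - phat)))


def deviance(fit: PsychometricFit, levels, n, k, eps=DEFAULT_EPS) -> float:
    """Deviance of a fit: 2 * (saturated log-likelihood - fitted log-likelihood)."""
    levels, n, k = _check_binned(levels, n, k)
    ll_fit = -negative_log_likelihood((fit.pse, fit.sigma, fit.lapse), levels, n, k, eps)
    dev = 2.0 * (_saturated_loglik(n, k) - ll_fit)
    return max(float(dev), 0.0)


def _start_grid(levels, n, k, lapse_max, fit_lapse):
    lo, hi = float(levels.min()), float(levels.max())
    # crude PSE guess: level where the empirical proportion crosses 1/2
    prop = k / n
    crossing = float(np.interp(0.5, np.clip(prop, 0, 1), levels)) if np.any(
        np.diff(prop) != 0
    ) else 0.5 * (lo + hi)
    pse_starts = np.unique([lo, 0.5 * (lo + hi), hi, np.clip(crossing, lo, hi)])
    lapse_starts = [s for s in _LAPSE_STARTS if s <= lapse_max] if fit_lapse else [0.0]
    starts = [
        (p0, s0, l0)
        for p0 in pse_starts
        for s0 in _SIGMA_STARTS
        for l0 in lapse_starts
    ]
    return starts


def fit_ml(
    levels,
    n,
    k,
    *,
    lapse_max: float = DEFAULT_LAPSE_MAX,
    fit_lapse: bool = True,
    eps: float = DEFAULT_EPS,
    n_local_starts: int = 3,
    x0: Optional[tuple] = None,
) -> PsychometricFit:
    """Maximum-likelihood fit of (pse, sigma, lapse) to binned 2-IFC data.

    Multi-start strategy: the NLL is evaluated on a deterministic start grid
    (PSE over the level range, sigma over {0.5, 1, 2, 4, 8}°, lapse over
    {0, 0.02}); bounded L-BFGS-B with analytic gradients is run from the
    ``n_local_starts`` best grid points (plus ``x0`` when given), with a
    Nelder-Mead fallback if no gradient run converges.

    Raises
    ------
    NonIdentifiableError
        If the responses are constant across all levels (the PSE is then
        unbounded in the direction of the constant response).
    """
    levels, n, k = _check_binned(levels, n, k)
    if levels.size < 3:
        raise InvalidInputError("need at least 3 distinct levels to fit")
    if np.all(k == 0) or np.all(k == n):
        raise NonIdentifiableError(
            "responses are constant at every level; the PSE is not identifiable "
            "(observer at an asymptote everywhere)"
        )
    span = float(levels.max() - levels.min())
    bounds = [
        (levels.min() - 2.0 * span, levels.max() + 2.0 * span),
        _SIGMA_BOUNDS,
        (0.0, lapse_max if fit_lapse else 0.0),
    ]

    if x0 is not None and n_local_starts <= 1:
        # bootstrap refits: start at the original solution only
        selected = [tuple(x0)]
    else:
        starts = _start_grid(levels, n, k, lapse_max, fit_lapse)
        scores = [_nll_raw(s, levels, n, k, eps) for s in starts]
        order = np.argsort(scores)
        selected = [starts[i] for i in order[:n_local_starts]]
        if x0 is not None:
            selected.insert(0, tuple(x0))

    best = None
    for s in selected:
        res = minimize(
            _nll_and_grad,
            x0=np.asarray(s, dtype=float),
            args=(levels, n, k, eps, fit_lapse),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-9, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not best.success:
        # gradient-free fallback from the best grid start
        res = minimize(
            lambda x: negative_log_likelihood(x, levels, n, k, eps),
            x0=np.asarray(selected[0], dtype=float),
            method="Nelder-Mead",
            options={"fatol": 1e-9, "xatol": 1e-7, "maxiter": 2000},
        )
        res.x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
        if best is None or res.fun < best.fun:
            best = res

    pse, sigma, lapse = (float(v) for v in best.x)
    fit = PsychometricFit(
        pse=pse,
        sigma=sigma,
        lapse=lapse,
        nll=float(best.fun),
        deviance=0.0,
        converged=bool(best.success),
        n_levels=int(levels.size),
        n_trials=int(n.sum()),
    )
    dev = deviance(fit, levels, n, k, eps)
    return PsychometricFit(
        pse, sigma, lapse, fit.nll, dev, fit.converged, fit.n_levels, fit.n_trials
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile confidence intervals from a parametric bootstrap."""

    ci: dict
    coverage: float
    n_samples: int
    n_failed: int
    seed: int
    high_failure_warning: bool = False


def parametric_bootstrap(
    fit: PsychometricFit,
    levels,
    n,
    k,
    n_samples: int = DEFAULT_N_BOOTSTRAP,
    coverage: float = 0.95,
    seed: int = 0,
    *,
    lapse_max: float = DEFAULT_LAPSE_MAX,
    fit_lapse: bool = True,
    eps: float = DEFAULT_EPS,
) -> BootstrapResult:
    """Parametric Monte-Carlo bootstrap confidence intervals.

    Simulates ``n_samples`` binomial datasets from the fitted curve at the
    observed levels and trial counts, refits each (started at the original
    solution), and returns percentile intervals for pse, sigma and lapse.
    Refit failures are dropped and counted; a failure fraction above 20%
    sets ``high_failure_warning``.
    """
    if not fit.converged:
        raise InvalidInputError("bootstrap requires a converged fit")
    levels, n, k = _check_binned(levels, n, k)
    rng = np.random.default_rng(seed)
    p_fit = fit.probability(levels)
    draws = rng.binomial(n.astype(int), p_fit, size=(int(n_samples), levels.size))
    samples = {"pse": [], "sigma": [], "lapse": []}
    n_failed = 0
    x0 = (fit.pse, fit.sigma, fit.lapse)
    for row in draws:
        try:
            refit = fit_ml(
                levels,
                n,
                row,
                lapse_max=lapse_max,
                fit_lapse=fit_lapse,
                eps=eps,
                n_local_starts=1,
                x0=x0,
            )
        except (NonIdentifiableError, InvalidInputError):
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        samples["pse"].append(refit.pse)
        samples["sigma"].append(refit.sigma)
        samples["lapse"].append(refit.lapse)
    alpha = 1.0 - coverage
    ci = {}
    for name, vals in samples.items():
        vals = np.asarray(vals)
        if vals.size == 0:
            ci[name] = (np.nan, np.nan)
        else:
            ci[name] = tuple(
                float(q)
                for q in np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            )
    return BootstrapResult(
        ci=ci,
        coverage=coverage,
        n_samples=int(n_samples),
        n_failed=n_failed,
        seed=int(seed),
        high_failure_warning=n_failed > 0.2 * n_samples,
    )


class CumulativeGaussianPsychometric(BaseEstimator):
    """Scikit-learn style cumulative-Gaussian psychometric estimator.

    Parameters
    ----------
    lapse_max : float, default 0.05
        Upper bound of the fitted lapse rate.
    fit_lapse : bool, default True
        Whether the lapse rate is fitted or fixed at zero.
    eps : float, default 1e-9
        Likelihood clamping bound.

    Attributes (after ``fit``)
    --------------------------
    pse_, sigma_, lapse_ : float
        Maximum-likelihood parameter estimates.
    nll_, deviance_ : float
        Negative log-likelihood and deviance against the saturated model.
    converged_ : bool
    fit_ : PsychometricFit
        The full fit record.

    Examples
    --------
    >>> est = CumulativeGaussianPsychometric().fit(theta[:, None], chose)
    >>> est.predict_proba(np.array([[0.8]]))
    """

    def __init__(self, lapse_max=DEFAULT_LAPSE_MAX, fit_lapse=True, eps=DEFAULT_EPS):
        self.lapse_max = lapse_max
        self.fit_lapse = fit_lapse
        self.eps = eps

    def _bin(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise InvalidInputError("X must be a single orientation column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise InvalidInputError("X and y must have equal length")
        if not np.all(np.isin(y, [0.0, 1.0])):
            raise InvalidInputError("y must be binary choice indicators")
        levels = np.unique(X)
        n = np.array([np.sum(X == lv) for lv in levels], dtype=float)
        k = np.array([np.sum(y[X == lv]) for lv in levels], dtype=float)
        return levels, n, k

    def fit(self, X, y):
        """Fit to trial-level data: X = orientations (n, 1), y = chose (0/1)."""
        levels, n, k = self._bin(X, y)
        res = fit_ml(
            levels, n, k, lapse_max=self.lapse_max, fit_lapse=self.fit_lapse,
            eps=self.eps,
        )
        self.levels_, self.n_, self.k_ = levels, n, k
        self.fit_ = res
        self.pse_ = res.pse
        self.sigma_ = res.sigma
        self.lapse_ = res.lapse
        self.nll_ = res.nll
        self.deviance_ = res.deviance
        self.converged_ = res.converged
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X):
        """Class probabilities [P(not chosen), P(chosen)] per trial."""
        X = np.asarray(X, dtype=float)
        theta = X[:, 0] if X.ndim == 2 else X
        p = self.fit_.probability(theta)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def bootstrap(self, n_samples=DEFAULT_N_BOOTSTRAP, coverage=0.95, seed=0):
        """Parametric bootstrap CIs for the fitted parameters."""
        return parametric_bootstrap(
            self.fit_, self.levels_, self.n_, self.k_,
            n_samples=n_samples, coverage=coverage, seed=seed,
            lapse_max=self.lapse_max, fit_lapse=self.fit_lapse, eps=self.eps,
        )
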