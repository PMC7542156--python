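"""Multilevel logistic regression with per-participant random intercepts and
slopes, plus the bank of comparison classifiers.

Model
-----
For window i of participant j with component scores X,

    P(Y_i = 1) = logit^-1(alpha_j + sum_k beta_{j,k} X_{i,k}),

with participant-level coefficients Gaussian around the population values:

    alpha_j ~ N(gamma_0, sigma_alpha^2),   beta_{j,k} ~ N(gamma_k, sigma_k^2),

mutually independent (diagonal random-effect covariance, one variance per
coefficient).  The marginal likelihood integrates the random effects out;
here the integral is approximated by the Laplace method — for each
participant the integrand is maximized over the random-effect vector by
Newton iterations (the problem is strictly concave) and a Gaussian
curvature correction applied.  Fixed effects and log standard deviations
are then maximized jointly by quasi-Newton ascent.  Per-participant effects
reported after fitting are the posterior modes.

Inference: Wald tests (observed-information standard errors) for the fixed
coefficients; likelihood-ratio tests against the model with one variance
component removed, referred to the boundary-corrected 1/2 chi2_0 + 1/2
chi2_1 mixture, for the random part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MultilevelLogisticRegression",
    "FitSummary",
    "fit_mlr",
    "predict_mlr",
    "fit_comparison",
    "COMPARISON_KINDS",
    "GROUP_MODEL_KINDS",
]


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


@dataclass
class FitSummary:
    """Per-coefficient fixed-effect inference and variance-component tests."""

    table: pd.DataFrame  # parameter, estimate, se, p_fixed, random_sd, p_random

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(index=False)


class MultilevelLogisticRegression(BaseEstimator, ClassifierMixin):
    """Mixed-effects logistic classifier (random intercepts and slopes).

    Parameters
    ----------
    random_intercept, random_slopes : which coefficients get a
        participant-level variance component.  With both False this is a
        plain logistic regression.
    min_sd, max_sd : box for the random-effect standard deviations during
        optimization; an estimate at ``min_sd`` is effectively zero.
    tol : relative convergence tolerance on the marginal log-likelihood.

    Attributes (after ``fit``)
    --------------------------
    gamma_ : population coefficients, length K+1 (intercept first).
    random_sds_ : standard deviations aligned with ``gamma_`` (0 where the
        coefficient has no random component).
    participant_effects_ : participant -> posterior-mode coefficient vector
        (length K+1, intercept first).
    loglik_ : maximized Laplace marginal log-likelihood.
    """

    def __init__(
        self,
        random_intercept: bool = True,
        random_slopes: bool = True,
        min_sd: float = 1e-3,
        max_sd: float = 10.0,
        tol: float = 1e-6,
        max_iter: int = 200,
    ):
        self.random_intercept = random_intercept
        self.random_slopes = random_slopes
        self.min_sd = min_sd
        self.max_sd = max_sd
        self.tol = tol
        self.max_iter = max_iter

    # -- internals -----------------------------------------------------------

    @staticmethod
    def _design(x: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(len(x)), x])

    def _re_index(self, k: int) -> np.ndarray:
        idx = []
        if self.random_intercept:
            idx.append(0)
        if self.random_slopes:
            idx.extend(range(1, k + 1))
        return np.array(idx, dtype=int)

    def _group_loglik(self, z, zr, y, gamma, sds, b0):
        """Laplace log-likelihood contribution of one participant.

        Returns (loglik, mode).  ``b0`` warm-starts the Newton search.
        """
        d_inv = 1.0 / sds**2
        offset = z @ gamma
        b = b0.copy()
        for _ in range(100):
            eta = offset + zr @ b
            p = _sigmoid(eta)
            grad = zr.T @ (y - p) - d_inv * b
            w = p * (1.0 - p)
            hess = (zr * w[:, None]).T @ zr + np.diag(d_inv)
            step = np.linalg.solve(hess, grad)
            # damped Newton: halve until the penalized objective improves
            f0 = np.sum(y * eta - _log1pexp(eta)) - 0.5 * np.sum(d_inv * b**2)
            t = 1.0
            for _ls in range(30):
                b_new = b + t * step
                eta_new = offset + zr @ b_new
                f_new = np.sum(y * eta_new - _log1pexp(eta_new)) - 0.5 * np.sum(
                    d_inv * b_new**2
                )
                if f_new >= f0:
                    break
                t *= 0.5
            b = b_new
            if np.max(np.abs(t * step)) < 1e-10:
                break
        eta = offset + zr @ b
        p = _sigmoid(eta)
        w = p * (1.0 - p)
        hess = (zr * w[:, None]).T @ zr + np.diag(d_inv)
        sign, logdet = np.linalg.slogdet(hess)
        ll = (
            np.sum(y * eta - _log1pexp(eta))
            - 0.5 * np.sum(d_inv * b**2)
            - np.sum(np.log(sds))
            - 0.5 * logdet
        )
        return ll, b

    def _neg_marginal(self, theta, groups_data, k, re_idx, warm):
        gamma = theta[: k + 1]
        sds = np.exp(theta[k + 1 :])
        total = 0.0
        for gid, (z, y) in groups_data.items():
            zr = z[:, re_idx]
            ll, b = self._group_loglik(z, zr, y, gamma, sds, warm[gid])
            warm[gid] = b
            total += ll
        return -total

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y, groups=None):
        x, y, groups, names = _coerce_xy(X, y, groups)
        self.feature_names_in_ = names
        self.classes_ = np.unique(y)
        k = x.shape[1]
        self.n_features_in_ = k
        uniq = pd.unique(groups)

        if len(uniq) < 2 or (not self.random_intercept and not self.random_slopes):
            if len(uniq) < 2:
                warnings.warn(
                    "single participant: falling back to ordinary logistic regression"
                )
            pooled = LogisticRegression(C=np.inf, max_iter=2000).fit(x, y)
            self.gamma_ = np.concatenate([pooled.intercept_, pooled.coef_.ravel()])
            self.random_sds_ = np.zeros(k + 1)
            self.participant_effects_ = {g: self.gamma_.copy() for g in uniq}
            self.loglik_ = float(
                np.sum(
                    y * (self._design(x) @ self.gamma_)
                    - _log1pexp(self._design(x) @ self.gamma_)
                )
            )
            self._theta_ = None
            return self

        re_idx = self._re_index(k)
        z = self._design(x)
        groups_data = {
            g: (z[groups == g], y[groups == g]) for g in uniq
        }
        warm = {g: np.zeros(len(re_idx)) for g in uniq}

        pooled = LogisticRegression(C=np.inf, max_iter=2000).fit(x, y)
        gamma0 = np.concatenate([pooled.intercept_, pooled.coef_.ravel()])
        theta0 = np.concatenate([gamma0, np.full(len(re_idx), np.log(0.5))])
        bounds = [(None, None)] * (k + 1) + [
            (np.log(self.min_sd), np.log(self.max_sd))
        ] * len(re_idx)

        res = optimize.minimize(
            self._neg_marginal,
            theta0,
            args=(groups_data, k, re_idx, warm),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": self.tol},
        )
        if not res.success and "ABNORMAL" in str(res.message):
            raise RuntimeError(f"multilevel fit did not converge: {res.message}")

        theta = res.x
        self._theta_ = theta
        self._re_idx_ = re_idx
        self._groups_data_ = groups_data
        self.gamma_ = theta[: k + 1]
        sds = np.exp(theta[k + 1 :])
        self.random_sds_ = np.zeros(k + 1)
        self.random_sds_[re_idx] = np.where(sds <= self.min_sd * 1.01, 0.0, sds)
        self.loglik_ = -res.fun

        self.participant_effects_ = {}
        for g, (zg, yg) in groups_data.items():
            _, b = self._group_loglik(zg, zg[:, re_idx], yg, self.gamma_, sds, warm[g])
            eff = self.gamma_.copy()
            eff[re_idx] += b
            self.participant_effects_[g] = eff
        return self

    def predict_proba(self, X, groups=None):
        x, _, groups, _ = _coerce_xy(X, None, groups)
        z = self._design(x)
        eta = np.empty(len(x))
        if groups is None:
            eta[:] = z @ self.gamma_
        else:
            for i in range(len(x)):
                coef = self.participant_effects_.get(groups[i], self.gamma_)
                eta[i] = z[i] @ coef
        p1 = _sigmoid(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, groups=None):
        return (self.predict_proba(X, groups)[:, 1] >= 0.5).astype(int)

    # -- inference -----------------------------------------------------------

    def _hessian(self, theta, groups_data, k, re_idx, step=1e-4):
        n = len(theta)
        warm = {g: np.zeros(len(re_idx)) for g in groups_data}
        h = np.empty((n, n))
        f = lambda t: self._neg_marginal(t, groups_data, k, re_idx, warm)
        steps = np.maximum(step, step * np.abs(theta))
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = steps[i]
                ej = np.zeros(n); ej[j] = steps[j]
                h[i, j] = h[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
        return h

    def covariance(self) -> np.ndarray:
        """Observed-information covariance of (gamma, log sd) at the optimum."""
        if getattr(self, "_theta_", None) is None:
            raise RuntimeError("no multilevel fit available")
        if not hasattr(self, "_cov_"):
            h = self._hessian(
                self._theta_, self._groups_data_, self.n_features_in_, self._re_idx_
            )
            self._cov_ = np.linalg.pinv(h)
        return self._cov_

    def summary(self, variance_tests: bool = True) -> FitSummary:
        """Table of fixed estimates, SEs, Wald p-values, random-effect SDs and
        boundary-corrected LRT p-values per variance component."""
        k = self.n_features_in_
        names = ["intercept"] + list(self.feature_names_in_)
        if getattr(self, "_theta_", None) is None:
            rows = [
                {"parameter": nm, "estimate": self.gamma_[i], "se": np.nan,
                 "p_fixed": np.nan, "random_sd": 0.0, "p_random": np.nan}
                for i, nm in enumerate(names)
            ]
            return FitSummary(pd.DataFrame(rows))
        cov = self.covariance()
        se = np.sqrt(np.maximum(np.diag(cov)[: k + 1], 0.0))
        zvals = np.divide(self.gamma_, se, out=np.full(k + 1, np.nan), where=se > 0)
        p_fixed = 2.0 * stats.norm.sf(np.abs(zvals))
        p_random = np.full(k + 1, np.nan)
        if variance_tests:
            for pos, idx in enumerate(self._re_idx_):
                p_random[idx] = self._variance_test(pos)
        rows = []
        for i, nm in enumerate(names):
            rows.append(
                {
                    "parameter": nm,
                    "estimate": self.gamma_[i],
                    "se": se[i],
                    "p_fixed": p_fixed[i],
                    "random_sd": self.random_sds_[i],
                    "p_random": p_random[i],
                }
            )
        return FitSummary(pd.DataFrame(rows))

    def _variance_test(self, pos: int) -> float:
        """LRT of sigma_q = 0 against the half-half chi-square mixture."""
        k = self.n_features_in_
        re_idx = self._re_idx_
        warm = {g: np.zeros(len(re_idx)) for g in self._groups_data_}
        theta0 = self._theta_.copy()
        j = k + 1 + pos
        lo = np.log(self.min_sd)
        theta0[j] = lo
        bounds = [(None, None)] * (k + 1) + [
            (np.log(self.min_sd), np.log(self.max_sd))
        ] * len(re_idx)
        bounds[j] = (lo, lo)  # pin this component at (numerically) zero
        res = optimize.minimize(
            self._neg_marginal,
            theta0,
            args=(self._groups_data_, k, re_idx, warm),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": self.tol},
        )
        lr = 2.0 * (self.loglik_ - (-res.fun))
        if lr <= 0:
            return 1.0
        return float(0.5 * stats.chi2.sf(lr, df=1))

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        """Wald intervals for gamma and (log-scale, exponentiated) for the SDs."""
        cov = self.covariance()
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        zq = stats.norm.ppf(0.5 + level / 2.0)
        theta = self._theta_
        k = self.n_features_in_
        rows = []
        names = ["intercept"] + list(self.feature_names_in_)
        for i in range(k + 1):
            rows.append(
                {"parameter": names[i], "estimate": theta[i],
                 "lo": theta[i] - zq * se[i], "hi": theta[i] + zq * se[i]}
            )
        for pos, idx in enumerate(self._re_idx_):
            j = k + 1 + pos
            rows.append(
                {
                    "parameter": f"sd({names[idx]})",
                    "estimate": np.exp(theta[j]),
                    "lo": np.exp(theta[j] - zq * se[j]),
                    "hi": np.exp(theta[j] + zq * se[j]),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# comparison-model bank
# ---------------------------------------------------------------------------

COMPARISON_KINDS = (
    "lr_varying_intercept",
    "lr_plain",
    "lr_stepwise_bic",
    "lr_individual",
    "knn",
    "svm_linear",
    "svm_cubic",
    "svm_gaussian",
    "decision_tree",
)

# the group-level report bank: the multilevel model plus every comparison
# model that is itself a single group-level fit
GROUP_MODEL_KINDS = (
    "mlr",
    "lr_varying_intercept",
    "lr_plain",
    "lr_stepwise_bic",
    "knn",
    "svm_linear",
    "svm_cubic",
    "svm_gaussian",
    "decision_tree",
)


class _SklearnAdapter(BaseEstimator, ClassifierMixin):
    """Uniform fit/predict_proba surface accepting an (ignored) groups arg."""

    def __init__(self, inner):
        self.inner = inner

    def fit(self, X, y, groups=None):
        x, y, _, names = _coerce_xy(X, y, groups)
        self.feature_names_in_ = names
        self.inner.fit(x, y)
        self.classes_ = self.inner.classes_
        return self

    def predict_proba(self, X, groups=None):
        x, _, _, _ = _coerce_xy(X, None, None)
        return self.inner.predict_proba(x)

    def predict(self, X, groups=None):
        x, _, _, _ = _coerce_xy(X, None, None)
        return self.inner.predict(x)


class StepwiseInteractionLogit(BaseEstimator, ClassifierMixin):
    """Forward-stepwise logistic regression over main effects and all two-way
    interactions, adding at each step the term that most lowers the BIC and
    stopping when no addition improves it."""

    def __init__(self, max_terms: int = 30):
        self.max_terms = max_terms

    @staticmethod
    def _term_column(x: np.ndarray, term: tuple[int, ...]) -> np.ndarray:
        col = np.ones(len(x))
        for i in term:
            col = col * x[:, i]
        return col

    def fit(self, X, y, groups=None):
        import statsmodels.api as sm

        x, y, _, names = _coerce_xy(X, y, groups)
        self.feature_names_in_ = names
        self.classes_ = np.unique(y)
        k = x.shape[1]
        candidates: list[tuple[int, ...]] = [(i,) for i in range(k)]
        candidates += [(i, j) for i in range(k) for j in range(i + 1, k)]
        chosen: list[tuple[int, ...]] = []

        def bic_for(terms):
            design = np.column_stack(
                [np.ones(len(x))] + [self._term_column(x, t) for t in terms]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            return fit.bic, fit

        best_bic, best_fit = bic_for([])
        improved = True
        while improved and len(chosen) < self.max_terms:
            improved = False
            best_add, best_add_bic, best_add_fit = None, best_bic, best_fit
            for t in candidates:
                if t in chosen:
                    continue
                try:
                    b, f = bic_for(chosen + [t])
                except Exception:
                    continue
                if b < best_add_bic - 1e-9:
                    best_add, best_add_bic, best_add_fit = t, b, f
            if best_add is not None:
                chosen.append(best_add)
                best_bic, best_fit = best_add_bic, best_add_fit
                improved = True
        self.terms_ = chosen
        self._fit_ = best_fit
        return self

    def _design(self, x):
        return np.column_stack(
            [np.ones(len(x))] + [self._term_column(x, t) for t in self.terms_]
        )

    def predict_proba(self, X, groups=None):
        x, _, _, _ = _coerce_xy(X, None, None)
        p1 = self._fit_.predict(self._design(x))
        return np.column_stack([1 - p1, p1])

    def predict(self, X, groups=None):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def term_names(self) -> list[str]:
        names = self.feature_names_in_
        return [":".join(names[i] for i in t) for t in self.terms_]


class PerParticipantLogit(BaseEstimator, ClassifierMixin):
    """One ordinary logistic regression per participant; a pooled fit serves
    participants unseen at training time."""

    def fit(self, X, y, groups=None):
        x, y, groups, names = _coerce_xy(X, y, groups)
        if groups is None:
            raise ValueError("lr_individual requires participant ids")
        self.feature_names_in_ = names
        self.classes_ = np.unique(y)
        self.models_ = {}
        for g in pd.unique(groups):
            m = (groups == g)
            if len(np.unique(y[m])) < 2:
                continue
            self.models_[g] = LogisticRegression(C=np.inf, max_iter=2000).fit(
                x[m], y[m]
            )
        self.pooled_ = LogisticRegression(C=np.inf, max_iter=2000).fit(x, y)
        return self

    def predict_proba(self, X, groups=None):
        x, _, groups, _ = _coerce_xy(X, None, groups)
        p1 = np.empty(len(x))
        for i in range(len(x)):
            model = self.pooled_ if groups is None else self.models_.get(
                groups[i], self.pooled_
            )
            p1[i] = model.predict_proba(x[i : i + 1])[0, 1]
        return np.column_stack([1 - p1, p1])

    def predict(self, X, groups=None):
        return (self.predict_proba(X, groups)[:, 1] >= 0.5).astype(int)


def fit_comparison(kind: str, X, y, groups=None, seed: int = 0, **config):
    """Fit one model of the comparison bank; returns the fitted estimator.

    ``kind`` is one of ``mlr`` or the entries of ``COMPARISON_KINDS``.
    All fitted models expose ``predict_proba(X, groups=None)``.
    """
    model = make_model(kind, seed=seed, **config)
    return model.fit(X, y, groups=groups)


def make_model(kind: str, seed: int = 0, **config):
    if kind == "mlr":
        return MultilevelLogisticRegression(**config)
    if kind == "lr_varying_intercept":
        return MultilevelLogisticRegression(random_slopes=False, **config)
    if kind == "lr_plain":
        return _SklearnAdapter(LogisticRegression(C=np.inf, max_iter=2000))
    if kind == "lr_stepwise_bic":
        return StepwiseInteractionLogit(**config)
    if kind == "lr_individual":
        return PerParticipantLogit()
    if kind == "knn":
        return _SklearnAdapter(KNeighborsClassifier(n_neighbors=config.get("k", 11)))
    if kind == "svm_linear":
        return _SklearnAdapter(SVC(kernel="linear", probability=True, random_state=seed))
    if kind == "svm_cubic":
        return _SklearnAdapter(
            SVC(kernel="poly", degree=3, probability=True, random_state=seed)
        )
    if kind == "svm_gaussian":
        return _SklearnAdapter(SVC(kernel="rbf", probability=True, random_state=seed))
    if kind == "decision_tree":
        return _SklearnAdapter(DecisionTreeClassifier(random_state=seed))
    raise ValueError(f"unknown model kind '{kind}'")


# -- thin functional wrappers -------------------------------------------------

def fit_mlr(scores, outcome, participant_ids, variance_tests: bool = True):
    """Fit the multilevel model; returns (model, FitSummary)."""
    model = MultilevelLogisticRegression().fit(scores, outcome, groups=participant_ids)
    return model, model.summary(variance_tests=variance_tests)


def predict_mlr(model: MultilevelLogisticRegression, scores, participant_ids=None):
    return model.predict_proba(scores, groups=participant_ids)[:, 1]


# ---------------------------------------------------------------------------

def _coerce_xy(X, y, groups):
    """Normalize inputs to (ndarray X, int y, object-array groups, names)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        x = X.to_numpy(dtype=float)
        index = X.index
    else:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i + 1}" for i in range(x.shape[1])]
        index = None
    if y is not None:
        y = np.asarray(y).astype(int)
        if len(y) != len(x):
            raise ValueError("X and y length mismatch")
    if groups is not None:
        groups = np.asarray(pd.Series(groups).to_numpy())
        if len(groups) != len(x):
            raise ValueError("X and groups length mismatch")
    return x, y, groups, names
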