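"""Two-stage dimension reduction: lasso feature selection then PCA.

Stage 1 fits an L1-penalized logistic regression path over the standardized
feature matrix (binary SIB outcome), chooses the penalty by cross-validated
deviance with the one-standard-error rule (the sparsest model whose CV
deviance is within one SE of the minimum), and keeps the features with
nonzero coefficients.  Stage 2 runs PCA on the standardized selected
features and keeps the smallest number of components reaching a cumulative
explained-variance target (default 65%), or a fixed component count when
requested.  The component scores feed the multilevel classifier.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = ["LassoSelector", "PCAReducer", "lasso_select", "pca_fit", "pca_transform"]


class LassoSelector(BaseEstimator):
    """L1-penalized logistic feature selection with a CV'd 1-SE penalty.

    Parameters
    ----------
    n_lambdas : size of the log-spaced penalty grid.
    folds : cross-validation folds for the deviance curve.
    lambda_ : optional fixed penalty; skips CV. ``lambda_=0`` fits the
        unpenalized logistic model (no selection pressure).
    seed : controls the CV fold assignment.

    Attributes (after ``fit``)
    --------------------------
    selected_names_ : features with nonzero coefficients, in input order.
    coefficients_ : coefficient vector over all input features (unselected
        entries exactly 0), on the standardized scale.
    lambda_ : the penalty used for the final fit.
    cv_curve_ : DataFrame (lambda, mean_deviance, se_deviance).
    """

    def __init__(
        self,
        n_lambdas: int = 40,
        folds: int = 10,
        lambda_: float | None = None,
        seed: int = 0,
    ):
        self.n_lambdas = n_lambdas
        self.folds = folds
        self.lambda_ = lambda_
        self.seed = seed

    # λ relates to sklearn's C by C = 1 / (n * λ) for mean-loss scaling
    @staticmethod
    def _fit_at(x: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
        if lam <= 0:
            model = LogisticRegression(C=np.inf, max_iter=2000)
        else:
            c = 1.0 / (len(y) * lam)
            model = LogisticRegression(
                l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000
            )
        model.fit(x, y)
        return model

    def fit(self, features: pd.DataFrame, y=None, outcome: str = "outcome"):
        x_df, y = _split_xy(features, y, outcome)
        if len(np.unique(y)) < 2:
            raise ValueError("outcome must contain both classes")
        names = list(x_df.columns)
        x = x_df.to_numpy(dtype=float)
        self.means_ = x.mean(axis=0)
        sds = x.std(axis=0)
        self.sds_ = np.where(sds > 0, sds, 1.0)
        xs = (x - self.means_) / self.sds_
        n = len(y)

        if self.lambda_ is not None:
            lam = float(self.lambda_)
            self.cv_curve_ = None
        else:
            # strongest penalty that admits any nonzero coefficient
            p_bar = y.mean()
            lam_max = np.max(np.abs(xs.T @ (y - p_bar))) / n
            lambdas = np.geomspace(lam_max, lam_max * 1e-4, self.n_lambdas)
            cv = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
            dev = np.empty((self.folds, len(lambdas)))
            for f, (tr, te) in enumerate(cv.split(xs, y)):
                for li, lam in enumerate(lambdas):
                    m = self._fit_at(xs[tr], y[tr], lam)
                    p = m.predict_proba(xs[te])[:, 1]
                    dev[f, li] = 2.0 * log_loss(y[te], p, labels=[0, 1])
            mean_dev = dev.mean(axis=0)
            se_dev = dev.std(axis=0, ddof=1) / np.sqrt(self.folds)
            best = int(np.argmin(mean_dev))
            limit = mean_dev[best] + se_dev[best]
            # sparsest (largest-penalty) model within one SE of the minimum
            ok = np.nonzero(mean_dev <= limit)[0]
            lam = float(lambdas[ok[0]])
            self.cv_curve_ = pd.DataFrame(
                {"lambda": lambdas, "mean_deviance": mean_dev, "se_deviance": se_dev}
            )

        final = self._fit_at(xs, y, lam)
        coefs = final.coef_.ravel()
        self.lambda_ = lam
        self.coefficients_ = coefs
        self.intercept_ = float(final.intercept_[0])
        self.feature_names_in_ = names
        self.selected_names_ = [nm for nm, c in zip(names, coefs) if c != 0.0]
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        """Restrict a table to the selected features (metadata untouched)."""
        missing = [nm for nm in self.selected_names_ if nm not in features.columns]
        if missing:
            raise ValueError(f"features missing selected columns: {missing}")
        return features[self.selected_names_]


class PCAReducer(TransformerMixin, BaseEstimator):
    """PCA on standardized features with a cumulative-variance stopping rule.

    ``n_components`` overrides the variance target with a fixed component
    count.  Zero-variance features are dropped with a warning.  Loadings use
    a deterministic sign convention: the largest-magnitude entry of each
    column is positive.
    """

    def __init__(self, variance_target_pct: float = 65.0, n_components: int | None = None):
        self.variance_target_pct = variance_target_pct
        self.n_components = n_components

    def fit(self, features: pd.DataFrame, y=None):
        x_df = features.select_dtypes(include=[np.number]) if not all(
            np.issubdtype(d, np.number) for d in features.dtypes
        ) else features
        names = list(x_df.columns)
        x = x_df.to_numpy(dtype=float)
        if x.shape[0] < 2 or x.shape[1] < 1:
            raise ValueError("need >= 2 rows and >= 1 feature")
        sds = x.std(axis=0)
        keep = sds > 0
        if not np.all(keep):
            dropped = [nm for nm, k in zip(names, keep) if not k]
            warnings.warn(f"dropping zero-variance features: {dropped}")
        self.feature_names_ = [nm for nm, k in zip(names, keep) if k]
        x = x[:, keep]
        self.means_ = x.mean(axis=0)
        self.sds_ = x.std(axis=0)
        xs = (x - self.means_) / self.sds_

        full = PCA(n_components=min(xs.shape), svd_solver="full")
        full.fit(xs)
        evr = full.explained_variance_ratio_ * 100.0
        if self.n_components is not None:
            p = int(self.n_components)
        else:
            cum = np.cumsum(evr)
            p = int(np.searchsorted(cum, self.variance_target_pct) + 1)
            p = min(p, len(evr))
        loadings = full.components_[:p].T  # (S, P)
        # sign convention: largest-|.| entry of each column positive
        flips = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
        flips[flips == 0] = 1.0
        self.loadings_ = loadings * flips
        self.explained_variance_pct_ = evr[:p]
        self.explained_variance_pct_full_ = evr
        self.n_components_ = p
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [nm for nm in self.feature_names_ if nm not in features.columns]
        if missing:
            raise ValueError(f"features missing columns: {missing}")
        x = features[self.feature_names_].to_numpy(dtype=float)
        xs = (x - self.means_) / self.sds_
        scores = xs @ self.loadings_
        return pd.DataFrame(
            scores,
            columns=[f"PC{i + 1}" for i in range(self.n_components_)],
            index=features.index,
        )

    def loadings_table(self) -> pd.DataFrame:
        """Loadings as a named table (feature x component), exportable."""
        return pd.DataFrame(
            self.loadings_,
            index=self.feature_names_,
            columns=[f"PC{i + 1}" for i in range(self.n_components_)],
        )


def _split_xy(features: pd.DataFrame, y, outcome: str):
    if y is not None:
        x_df = features
        y = np.asarray(y)
    else:
        if outcome not in features.columns:
            raise ValueError(f"no '{outcome}' column and no y given")
        y = features[outcome].to_numpy()
        drop = [c for c in ("participant_id", "start_s", outcome) if c in features.columns]
        x_df = features.drop(columns=drop)
    x_df = x_df.select_dtypes(include=[np.number])
    return x_df, y.astype(int)


# -- thin functional wrappers -------------------------------------------------

def lasso_select(features: pd.DataFrame, outcome: str = "outcome",
                 folds: int = 10, seed: int = 0) -> LassoSelector:
    return LassoSelector(folds=folds, seed=seed).fit(features, outcome=outcome)


def pca_fit(features: pd.DataFrame, variance_target_pct: float = 65.0,
            n_components: int | None = None) -> PCAReducer:
    return PCAReducer(variance_target_pct=variance_target_pct,
                      n_components=n_components).fit(features)


def pca_transform(model: PCAReducer, features: pd.DataFrame) -> pd.DataFrame:
    return model.transform(features)
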