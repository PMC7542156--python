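"""Evaluation protocol: class balancing, 80/20 split, tenfold CV, balanced
and natural-ratio test sets, the five classification metrics, adjusted
pseudo-R^2, and the end-to-end pipeline runner.

The window-level class distribution is heavily skewed (SIB windows are
rare), so training uses random undersampling of the majority class to
equality.  The held-out 20% is evaluated twice: balanced (undersampled to
equality, probing discrimination) and at the natural class ratio (probing
deployment conditions, where precision collapses even for a good ranker).
Splits are stratified jointly by participant and class so every participant
contributes to training — a requirement for participant-level random
effects.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import ALL_FEATURE_NAMES, extract_features
from .models import GROUP_MODEL_KINDS, MultilevelLogisticRegression, make_model
from .preprocess import segment_windows
from .reduction import LassoSelector, PCAReducer
from .synthetic import CohortSpec, generate_cohort

__all__ = [
    "SplitSpec",
    "EvalReport",
    "PipelineConfig",
    "balance_classes",
    "split_train_test",
    "cross_validate",
    "compute_metrics",
    "adjusted_r2",
    "run_pipeline",
]


@dataclass(frozen=True)
class SplitSpec:
    train_val_fraction: float = 0.8
    cv_folds: int = 10
    balance_train: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_val_fraction < 1):
            raise ValueError("train_val_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class EvalReport:
    accuracy: float
    specificity: float
    precision: float
    recall: float
    f_score: float
    adjusted_r2: float = np.nan
    train_time_per_obs_s: float = np.nan
    predict_time_per_obs_s: float = np.nan
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "adjusted_r2": self.adjusted_r2,
            "train_time_per_obs_s": self.train_time_per_obs_s,
            "predict_time_per_obs_s": self.predict_time_per_obs_s,
        }


def balance_classes(rows: pd.DataFrame, seed: int, outcome: str = "outcome") -> pd.DataFrame:
    """Random undersampling of the majority class to exact equality."""
    y = rows[outcome].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance")
    n_min = counts.min()
    if counts.max() == n_min:
        return rows
    rng = np.random.default_rng(seed)
    keep_idx = []
    for c, n_c in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        if n_c > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep_idx.append(idx)
    keep = np.sort(np.concatenate(keep_idx))
    return rows.iloc[keep]


def split_train_test(
    rows: pd.DataFrame, spec: SplitSpec, outcome: str = "outcome"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(train_val, balanced test, natural-ratio test), stratified by
    participant and class.

    Both test variants are drawn from the same held-out pool: the natural
    test set is the pool itself (its class ratio matches the full data
    within rounding), the balanced test set undersamples it to equality.
    Train and test never share a row.
    """
    rng = np.random.default_rng(spec.seed)
    y = rows[outcome].to_numpy()
    pid = rows["participant_id"].to_numpy()
    test_mask = np.zeros(len(rows), dtype=bool)
    for g in pd.unique(pid):
        for c in (0, 1):
            idx = np.flatnonzero((pid == g) & (y == c))
            if len(idx) == 0:
                continue
            n_test = int(round((1 - spec.train_val_fraction) * len(idx)))
            chosen = rng.choice(idx, size=n_test, replace=False)
            test_mask[chosen] = True
    train = rows.iloc[~test_mask]
    natural_test = rows.iloc[test_mask]
    if len(np.unique(train[outcome])) < 2 or len(np.unique(natural_test[outcome])) < 2:
        counts = rows.groupby(["participant_id", outcome]).size()
        raise ValueError(f"cannot stratify split; class counts:\n{counts}")
    balanced_test = balance_classes(natural_test, seed=spec.seed + 1, outcome=outcome)
    return train, balanced_test, natural_test


def compute_metrics(
    predicted: np.ndarray, true: np.ndarray, probabilities: np.ndarray | None = None,
    n_parameters: int = 1,
) -> EvalReport:
    """The five classification metrics (plus optional adjusted pseudo-R^2).

    Ratios with zero denominators are reported as 0 and flagged rather than
    NaN, so sweeps over degenerate folds keep running.
    """
    predicted = np.asarray(predicted).astype(int)
    true = np.asarray(true).astype(int)
    if len(predicted) != len(true):
        raise ValueError("predicted and true label lengths differ")
    tp = int(np.sum((predicted == 1) & (true == 1)))
    tn = int(np.sum((predicted == 0) & (true == 0)))
    fp = int(np.sum((predicted == 1) & (true == 0)))
    fn = int(np.sum((predicted == 0) & (true == 1)))
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, len(true), "accuracy")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f_score = ratio(2 * precision * recall, precision + recall, "f_score")
    adj = np.nan
    if probabilities is not None:
        adj = adjusted_r2(probabilities, true, n_parameters)
    return EvalReport(
        accuracy=accuracy, specificity=specificity, precision=precision,
        recall=recall, f_score=f_score, adjusted_r2=adj, flags=tuple(flags),
    )


def adjusted_r2(fitted_probabilities: np.ndarray, outcome: np.ndarray, n_parameters: int) -> float:
    """Squared correlation between outcome and fitted probability, adjusted
    for model size: 1 - (1 - R^2) (n - 1)/(n - p - 1)."""
    p_hat = np.asarray(fitted_probabilities, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if n <= n_parameters + 1:
        return np.nan
    if p_hat.std() == 0 or y.std() == 0:
        return 0.0
    r2 = float(np.corrcoef(y, p_hat)[0, 1] ** 2)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_parameters - 1)


def _model_n_params(model) -> int:
    gamma = getattr(model, "gamma_", None)
    if gamma is not None:
        return len(gamma)
    names = getattr(model, "feature_names_in_", None)
    return (len(names) + 1) if names is not None else 1


def _fit_and_eval(kind, train, test, score_cols, seed, outcome="outcome"):
    """Fit one model kind on train and evaluate on test; returns the report."""
    x_tr, y_tr, g_tr = train[score_cols], train[outcome].to_numpy(), train["participant_id"].to_numpy()
    x_te, y_te, g_te = test[score_cols], test[outcome].to_numpy(), test["participant_id"].to_numpy()
    model = make_model(kind, seed=seed)
    t0 = time.perf_counter()
    model.fit(x_tr, y_tr, groups=g_tr)
    t_train = (time.perf_counter() - t0) / len(y_tr)
    t0 = time.perf_counter()
    proba = model.predict_proba(x_te, groups=g_te)[:, 1]
    t_pred = (time.perf_counter() - t0) / len(y_te)
    rep = compute_metrics(
        (proba >= 0.5).astype(int), y_te, probabilities=proba,
        n_parameters=_model_n_params(model),
    )
    rep.train_time_per_obs_s = t_train
    rep.predict_time_per_obs_s = t_pred
    return rep


def cross_validate(
    kind: str,
    train_val: pd.DataFrame,
    spec: SplitSpec,
    score_cols: list[str],
    outcome: str = "outcome",
) -> tuple[list[EvalReport], EvalReport]:
    """Stratified k-fold CV of one model kind; returns (per-fold, mean)."""
    y = train_val[outcome].to_numpy()
    counts = np.bincount(y.astype(int))
    if counts.min() < spec.cv_folds:
        raise ValueError(
            f"{spec.cv_folds}-fold CV needs >= {spec.cv_folds} rows per class, "
            f"have {counts.tolist()}"
        )
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    reports = []
    for tr_idx, te_idx in cv.split(train_val, y):
        rep = _fit_and_eval(
            kind, train_val.iloc[tr_idx], train_val.iloc[te_idx],
            score_cols, seed=spec.seed, outcome=outcome,
        )
        reports.append(rep)
    mean_rep = EvalReport(
        **{
            k: float(np.mean([r.as_dict()[k] for r in reports]))
            for k in reports[0].as_dict()
        }
    )
    return reports, mean_rep


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort run."""

    cohort: CohortSpec
    split: SplitSpec = field(default_factory=SplitSpec)
    model_kinds: tuple[str, ...] = GROUP_MODEL_KINDS
    variance_target_pct: float = 65.0
    n_components: int | None = None
    lasso_folds: int = 10
    seed: int = 0


@dataclass
class PipelineReport:
    features: pd.DataFrame
    selected_features: list[str]
    n_components: int
    explained_variance_pct: np.ndarray
    validation: pd.DataFrame      # mean CV metrics per model kind
    test_balanced: pd.DataFrame
    test_natural: pd.DataFrame
    mlr_summary: pd.DataFrame | None


def run_pipeline(config: PipelineConfig, log=None) -> PipelineReport:
    """Generate -> preprocess -> featurize (96) -> lasso -> PCA -> fit the
    model bank -> evaluate with tenfold CV plus balanced and natural test
    sets.  Deterministic given ``config``'s seeds."""

    def _log(msg):
        if log is not None:
            log(msg)

    _log(f"generating cohort: {config.cohort.n_participants} participants, "
         f"seed {config.cohort.seed}")
    sessions = generate_cohort(config.cohort)
    frames = []
    for s in sessions:
        _log(f"  featurizing {s.participant_id}: {s.duration_s:.0f}s")
        frames.append(extract_features(segment_windows(s)))
    features = pd.concat(frames, ignore_index=True)
    assert sum(c in ALL_FEATURE_NAMES for c in features.columns) == 96

    _log("lasso feature selection")
    lasso = LassoSelector(folds=config.lasso_folds, seed=config.seed).fit(features)
    selected = lasso.selected_names_
    if not selected:  # fully shrunk: fall back to the full feature set
        selected = [c for c in features.columns if c in ALL_FEATURE_NAMES]
    _log(f"  selected {len(selected)} features (lambda={lasso.lambda_:.4g})")

    pca = PCAReducer(
        variance_target_pct=config.variance_target_pct,
        n_components=config.n_components,
    ).fit(features[[c for c in selected if c != "prompt"]])
    scores = pca.transform(features)
    score_cols = list(scores.columns)
    data = pd.concat(
        [features[["participant_id", "start_s", "outcome", "prompt"]], scores], axis=1
    )
    _log(f"  {pca.n_components_} components, "
         f"{pca.explained_variance_pct_.sum():.1f}% variance")

    train_val, test_bal, test_nat = split_train_test(data, config.split)
    if config.split.balance_train:
        train_val = balance_classes(train_val, seed=config.split.seed)

    rows_val, rows_bal, rows_nat = [], [], []
    mlr_summary = None
    for kind in config.model_kinds:
        _log(f"model {kind}")
        try:
            _, mean_rep = cross_validate(kind, train_val, config.split, score_cols)
        except ValueError:
            # too few minority rows for the full fold count: halve folds
            small = SplitSpec(
                train_val_fraction=config.split.train_val_fraction,
                cv_folds=max(2, config.split.cv_folds // 2),
                seed=config.split.seed,
            )
            _, mean_rep = cross_validate(kind, train_val, small, score_cols)
        rows_val.append({"model": kind, **mean_rep.as_dict()})
        rep_bal = _fit_and_eval(kind, train_val, test_bal, score_cols, config.seed)
        rep_nat = _fit_and_eval(kind, train_val, test_nat, score_cols, config.seed)
        rows_bal.append({"model": kind, **rep_bal.as_dict()})
        rows_nat.append({"model": kind, **rep_nat.as_dict()})
        if kind == "mlr":
            m = MultilevelLogisticRegression().fit(
                train_val[score_cols], train_val["outcome"].to_numpy(),
                groups=train_val["participant_id"].to_numpy(),
            )
            mlr_summary = m.summary(variance_tests=False).table

    return PipelineReport(
        features=features,
        selected_features=list(selected),
        n_components=pca.n_components_,
        explained_variance_pct=pca.explained_variance_pct_,
        validation=pd.DataFrame(rows_val),
        test_balanced=pd.DataFrame(rows_bal),
        test_natural=pd.DataFrame(rows_nat),
        mlr_summary=mlr_summary,
    )
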