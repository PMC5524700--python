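"""Exhaustive PLS model search over train/test splits.

Ten non-external codes are split into every possible 7-code training set
and 3-code test set (C(10,3) = 120 splits). For each split a PLS1
regression of kcat on the selected descriptors is fitted, scored by
leave-one-out q^2 on the training set and by q^2/RMSE on the test set,
and the surviving models (q2_test and rmse_test cutoffs) are ranked by
ascending test RMSE. Ranked models then predict the two held-out external
codes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .errors import FitError, GridQSARError
from .selection import DescriptorMatrix

__all__ = [
    "SplitPlan", "PLSModel", "ModelScore", "enumerate_splits", "fit_pls",
    "predict", "loo_q2", "q_squared", "rmse", "evaluate", "run_split",
    "run_all_splits", "rank_models", "predict_external",
]


@dataclass(frozen=True)
class SplitPlan:
    """One 7/3 train/test partition (external codes held aside)."""

    train_codes: tuple[str, ...]
    test_codes: tuple[str, ...]
    external_codes: tuple[str, ...] = ()

    @property
    def id(self) -> str:
        return "".join(self.test_codes)

    def __post_init__(self):
        overlap = set(self.train_codes) & set(self.test_codes)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")
        if set(self.external_codes) & (set(self.train_codes)
                                       | set(self.test_codes)):
            raise ValueError("external codes overlap train/test")


def enumerate_splits(codes, test_size: int = 3,
                     external=()) -> list[SplitPlan]:
    """All C(n, test_size) splits in deterministic lexicographic order."""
    codes = sorted(codes)
    external = tuple(sorted(external))
    if len(set(codes)) != len(codes):
        raise ValueError("codes must be distinct")
    if set(external) & set(codes):
        raise ValueError("external codes must be disjoint from split codes")
    if test_size >= len(codes):
        raise ValueError("test_size must be smaller than the code count")
    plans = []
    for test in itertools.combinations(codes, test_size):
        train = tuple(c for c in codes if c not in test)
        plans.append(SplitPlan(train_codes=train, test_codes=test,
                               external_codes=external))
    return plans


@dataclass
class PLSModel:
    """A fitted PLS1 regression in original-descriptor coordinates.

    Prediction is exactly ``X @ coefficients + intercept``; the
    coefficients fold in the centering (and optional autoscaling) applied
    during fitting.
    """

    labels: tuple[str, ...] | None
    coefficients: np.ndarray
    intercept: float
    n_components: int
    x_mean: np.ndarray = field(repr=False, default=None)
    y_mean: float = 0.0

    def coefficient_series(self) -> pd.Series:
        labels = (list(self.labels) if self.labels is not None
                  else [f"x{i}" for i in range(self.coefficients.size)])
        return pd.Series(self.coefficients, index=labels)


def _as_xy(X, y, labels=None):
    if isinstance(X, DescriptorMatrix):
        X = X.data
    if isinstance(X, pd.DataFrame):
        labels = tuple(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        labels = tuple(labels) if labels is not None else None
    if isinstance(y, pd.Series):
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    return Xv, yv, labels


def fit_pls(X, y, n_components: int = 2, autoscale: bool = False,
            labels=None) -> PLSModel:
    """Fit a PLS1 regression of activity on descriptors.

    Centering only by default (``autoscale=True`` adds unit-variance
    scaling). ``n_components`` must lie in [1, min(n-1, p)]. Deterministic:
    identical inputs give identical coefficients.
    """
    Xv, yv, labels = _as_xy(X, y, labels)
    n, p = Xv.shape
    if n != yv.size:
        raise FitError("X rows and y length differ")
    if n < 3:
        raise FitError("need >= 3 training samples")
    if yv.std() <= 0:
        raise FitError("constant y: nothing to regress")
    if np.abs(Xv - Xv.mean(axis=0)).max() <= 0:
        raise FitError("degenerate X: all columns constant")
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise FitError(
            f"n_components must be in [1, {max_comp}], got {n_components}")
    pls = PLSRegression(n_components=n_components, scale=autoscale)
    pls.fit(Xv, yv)
    coef = np.asarray(pls.coef_, dtype=float).reshape(-1)
    x_mean = Xv.mean(axis=0)
    y_mean = float(yv.mean())
    # coef_ is already on the original-X scale; fold the centering into a
    # plain affine intercept so prediction is exactly X @ coef + intercept
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(labels=labels, coefficients=coef, intercept=intercept,
                    n_components=n_components, x_mean=x_mean, y_mean=y_mean)


def predict(model: PLSModel, X) -> np.ndarray:
    """Deterministic linear prediction; checks column alignment."""
    if isinstance(X, DescriptorMatrix):
        X = X.data
    if isinstance(X, pd.DataFrame):
        if model.labels is not None and tuple(X.columns) != tuple(model.labels):
            raise GridQSARError("descriptor columns misaligned with model")
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.shape[-1] != model.coefficients.size:
            raise GridQSARError("descriptor columns misaligned with model")
    return Xv @ model.coefficients + model.intercept


def q_squared(y_true, y_pred, reference_mean: float | None = None) -> float:
    """1 - PRESS / total sum of squares about ``reference_mean`` (default:
    the mean of ``y_true`` itself)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mean = float(y_true.mean()) if reference_mean is None else reference_mean
    tss = float(((y_true - mean) ** 2).sum())
    if tss <= 0:
        raise GridQSARError("zero total sum of squares; q^2 undefined")
    return 1.0 - float(((y_true - y_pred) ** 2).sum()) / tss


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def loo_q2(X, y, n_components: int = 2, autoscale: bool = False) -> float:
    """Leave-one-out cross-validated q^2: each sample predicted by a model
    fitted without it, PRESS referenced to the full-sample mean."""
    Xv, yv, labels = _as_xy(X, y)
    n = Xv.shape[0]
    if n < 3:
        raise FitError("need >= 3 samples for leave-one-out")
    if yv.std() <= 0:
        raise FitError("constant y")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        k = min(n_components, mask.sum() - 1)
        model = fit_pls(Xv[mask], yv[mask], n_components=k,
                        autoscale=autoscale, labels=labels)
        preds[i] = predict(model, Xv[i:i + 1])[0]
    return q_squared(yv, preds)


def evaluate(model: PLSModel, X, y) -> tuple[float, float]:
    """(q^2, RMSE) of a fitted model on an evaluation set.

    q^2 is referenced to the evaluation set's own mean.
    """
    yhat = predict(model, X)
    return q_squared(y, yhat), rmse(y, yhat)


@dataclass
class ModelScore:
    """Statistics of one split's model."""

    split_id: str
    n_components: int
    q2_train_loo: float
    r2_train: float
    rmse_train: float
    q2_test: float
    rmse_test: float
    rmse_external: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _pick_components(X, y, max_components: int, autoscale: bool) -> int:
    """Latent-variable count maximizing training LOO q^2 over 1..max."""
    n, p = np.asarray(X).shape
    upper = max(1, min(max_components, n - 2, p))
    best_k, best_q = 1, -np.inf
    for k in range(1, upper + 1):
        q = loo_q2(X, y, n_components=k, autoscale=autoscale)
        if q > best_q + 1e-12:
            best_k, best_q = k, q
    return best_k


def run_split(matrix: DescriptorMatrix, activities: pd.Series, plan: SplitPlan,
              n_components: int | str = 2, autoscale: bool = False
              ) -> tuple[PLSModel, ModelScore]:
    """Fit and score one split; ``n_components='auto'`` picks the count by
    maximizing training LOO q^2 (up to 5)."""
    Xtr = matrix.rows(plan.train_codes)
    ytr = activities.loc[list(plan.train_codes)]
    Xte = matrix.rows(plan.test_codes)
    yte = activities.loc[list(plan.test_codes)]
    if n_components == "auto":
        k = _pick_components(Xtr, ytr, max_components=5, autoscale=autoscale)
    else:
        k = min(int(n_components), len(plan.train_codes) - 1,
                matrix.shape[1])
    model = fit_pls(Xtr, ytr, n_components=k, autoscale=autoscale)
    q2_tr, rmse_tr = evaluate(model, Xtr, ytr)
    q2_te, rmse_te = evaluate(model, Xte, yte)
    score = ModelScore(
        split_id=plan.id,
        n_components=k,
        q2_train_loo=loo_q2(Xtr, ytr, n_components=k, autoscale=autoscale),
        r2_train=q2_tr,
        rmse_train=rmse_tr,
        q2_test=q2_te,
        rmse_test=rmse_te,
    )
    return model, score


def run_all_splits(matrix: DescriptorMatrix, activities: pd.Series,
                   plans, n_components: int | str = 2,
                   autoscale: bool = False
                   ) -> tuple[dict[str, PLSModel], list[ModelScore]]:
    """Fit every split; returns models keyed by split id plus all scores."""
    models, scores = {}, []
    for plan in plans:
        model, score = run_split(matrix, activities, plan,
                                 n_components=n_components,
                                 autoscale=autoscale)
        models[plan.id] = model
        scores.append(score)
    return models, scores


def rank_models(scores, q2_min: float = 0.1,
                rmse_max: float = 40.0) -> list[ModelScore]:
    """Filter by q2_test > q2_min and rmse_test < rmse_max; sort by
    ascending test RMSE, ties by descending q2_test then split id."""
    passing = [s for s in scores
               if s.q2_test > q2_min and s.rmse_test < rmse_max]
    return sorted(passing, key=lambda s: (s.rmse_test, -s.q2_test, s.split_id))


def predict_external(model: PLSModel, X_ext) -> np.ndarray:
    """Predict kcat of the external validation codes (no clipping)."""
    return predict(model, X_ext)
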