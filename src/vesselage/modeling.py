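"""Age-regression modeling: six model families, four-fold cross-validation,
the four evaluation metrics, impurity-based feature importances and
real-vs-predicted scatter plots.

Model families ship with a fixed reference hyperparameter configuration;
the ``xgb_style_boosting`` family is a regularized gradient-boosted tree
ensemble whose xgb-style controls (``colsample_bytree``,
``gamma``, ``subsample``, ...) are mapped onto the scikit-learn
``GradientBoostingRegressor`` equivalents, so no external boosting library
is required.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import BayesianRidge, LinearRegression

__all__ = [
    "FAMILIES",
    "TREE_FAMILIES",
    "DEFAULT_HYPERPARAMETERS",
    "Metrics",
    "ModelSpec",
    "SearchResult",
    "ModelCVResult",
    "CVResult",
    "evaluate",
    "assign_folds",
    "build_estimator",
    "randomized_search",
    "run_cv",
    "feature_importance",
    "scatter_plot",
    "metrics_frame",
]

FAMILIES = (
    "random_forest",
    "linear",
    "adaboost",
    "gradient_boosting",
    "bayesian_ridge",
    "xgb_style_boosting",
)

TREE_FAMILIES = frozenset({"random_forest", "adaboost", "gradient_boosting", "xgb_style_boosting"})

#: Reference default hyperparameters per family (used verbatim when
#: randomized search is disabled).
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "random_forest": {
        "n_estimators": 74,
        "max_depth": 14,
        "min_samples_leaf": 2,
        "min_samples_split": 6,
        "max_features": "sqrt",
        "criterion": "absolute_error",
    },
    "linear": {},
    "adaboost": {"learning_rate": 0.07, "loss": "exponential", "n_estimators": 163},
    "gradient_boosting": {
        "criterion": "friedman_mse",
        "learning_rate": 0.11,
        "loss": "absolute_error",
        "max_depth": 15,
        "n_estimators": 198,
        "tol": 0.003,
    },
    "bayesian_ridge": {
        "alpha_1": 0.0004,
        "alpha_2": 1e-6,
        "alpha_init": 10.0,
        "lambda_1": 1e-5,
        "tol": 0.01,
    },
    "xgb_style_boosting": {
        "colsample_bytree": 0.95,
        "gamma": 0.22,
        "learning_rate": 0.30,
        "max_depth": 4,
        "n_estimators": 138,
        "subsample": 0.84,
    },
}

_EXTRA_ALLOWED: dict[str, set] = {
    "random_forest": {"min_impurity_decrease", "bootstrap", "max_leaf_nodes"},
    "adaboost": set(),
    "gradient_boosting": {"subsample", "max_features", "min_samples_leaf", "min_samples_split"},
    "bayesian_ridge": {"lambda_2", "lambda_init", "max_iter"},
    "linear": {"fit_intercept"},
    "xgb_style_boosting": {"min_child_weight", "reg_lambda"},
}

# xgb-style name -> GradientBoostingRegressor name (reg_lambda / min_child_weight
# have no exact sklearn equivalent and are approximated by leaf constraints)
_XGB_PARAM_MAP = {
    "colsample_bytree": "max_features",
    "gamma": "min_impurity_decrease",
    "subsample": "subsample",
    "learning_rate": "learning_rate",
    "max_depth": "max_depth",
    "n_estimators": "n_estimators",
    "min_child_weight": "min_samples_leaf",
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus hyperparameters and an optional search space."""

    family: str
    params: Mapping[str, object] = field(default_factory=dict)
    search_space: Mapping[str, object] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        allowed = set(DEFAULT_HYPERPARAMETERS[self.family]) | _EXTRA_ALLOWED[self.family]
        for source in (self.params, self.search_space or {}):
            unknown = [k for k in source if k not in allowed]
            if unknown:
                raise ValueError(
                    f"unknown hyperparameters for family {self.family!r}: {sorted(unknown)}"
                )

    def resolved_params(self) -> dict:
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.params)
        return merged


def default_model_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(family=f, seed=seed) for f in FAMILIES]


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a spec."""
    p = spec.resolved_params()
    if spec.family == "random_forest":
        return RandomForestRegressor(random_state=spec.seed, **p)
    if spec.family == "linear":
        return LinearRegression(**p)
    if spec.family == "adaboost":
        return AdaBoostRegressor(random_state=spec.seed, **p)
    if spec.family == "gradient_boosting":
        p = dict(p)
        # friedman_mse is sklearn's fixed split criterion; the key is kept in
        # the registry for completeness but not forwarded (deprecated arg)
        p.pop("criterion", None)
        return GradientBoostingRegressor(random_state=spec.seed, **p)
    if spec.family == "bayesian_ridge":
        return BayesianRidge(**p)
    if spec.family == "xgb_style_boosting":
        mapped = {_XGB_PARAM_MAP[k]: v for k, v in p.items() if k in _XGB_PARAM_MAP}
        return GradientBoostingRegressor(random_state=spec.seed, **mapped)
    raise AssertionError(spec.family)


@dataclass(frozen=True)
class Metrics:
    """Pearson r, RMSE (years), MAPE (fraction) and R^2 of an (x, y) pair."""

    r: float
    rmse: float
    mape: float
    r2: float
    notes: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"r": self.r, "rmse": self.rmse, "mape": self.mape, "r2": self.r2}


def evaluate(x, y) -> Metrics:
    """Evaluate predicted ages ``y`` against real ages ``x``.

    r = cov / (sd_x sd_y); RMSE = sqrt(mean (x-y)^2); MAPE = mean |x-y|/x;
    R^2 = 1 - SSE / SST.  Constant x or y leaves r (and R^2, for constant x)
    undefined: reported as NaN with an explanatory note.  Non-positive real
    ages make MAPE undefined and are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1D arrays, got {x.shape} and {y.shape}")
    if len(x) < 2:
        raise ValueError("at least 2 samples are required")
    if np.any(x <= 0):
        raise ValueError("real ages must be > 0 (MAPE denominator)")
    notes: list[str] = []
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0.0 or syy == 0.0:
        r = float("nan")
        notes.append("pearson r undefined: constant x or y")
    else:
        r = float(np.sum(dx * dy) / np.sqrt(sxx * syy))
    sse = float(np.sum((x - y) ** 2))
    rmse = float(np.sqrt(sse / len(x)))
    mape = float(np.mean(np.abs(x - y) / x))
    if sxx == 0.0:
        r2 = float("nan")
        notes.append("R^2 undefined: constant x")
    else:
        r2 = 1.0 - sse / sxx
    return Metrics(r=r, rmse=rmse, mape=mape, r2=r2, notes=tuple(notes))


def assign_folds(subject_ids: Sequence, k: int, seed: int = 0) -> np.ndarray:
    """Random fold label in [0, k) per subject; sizes differ by at most 1."""
    n = len(subject_ids)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = fold
    return labels


@dataclass
class SearchResult:
    spec: ModelSpec
    best_score_mae: float | None = None
    n_evaluated: int = 0
    warnings: tuple[str, ...] = ()


def _sample_param(rng: np.random.Generator, space):
    if hasattr(space, "rvs"):
        return space.rvs(random_state=rng)
    options = list(space)
    return options[int(rng.integers(len(options)))]


def randomized_search(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 20,
    seed: int = 0,
    inner_k: int = 3,
) -> SearchResult:
    """Randomized hyperparameter search on the training portion only.

    Candidates are scored by mean absolute error over an inner ``inner_k``-fold
    split of the training data; deterministic under ``seed``.  An empty
    search space returns the spec unchanged with a warning record.
    """
    if not spec.search_space:
        return SearchResult(spec=spec, warnings=("empty search space: spec returned unchanged",))
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    inner = assign_folds(np.arange(len(y)), inner_k, seed=seed)
    best_params, best_score = None, np.inf
    for _ in range(n_iter):
        cand = dict(spec.params)
        cand.update({k: _sample_param(rng, v) for k, v in spec.search_space.items()})
        cand_spec = replace(spec, params=cand, search_space=None)
        maes = []
        for f in range(inner_k):
            tr, va = inner != f, inner == f
            est = build_estimator(cand_spec)
            est.fit(X[tr], y[tr])
            maes.append(float(np.mean(np.abs(y[va] - est.predict(X[va])))))
        score = float(np.mean(maes))
        if score < best_score:
            best_params, best_score = cand, score
    return SearchResult(
        spec=replace(spec, params=best_params, search_space=None),
        best_score_mae=best_score,
        n_evaluated=n_iter,
    )


def feature_importance(model, feature_names: Sequence[str]) -> list[tuple[str, float]]:
    """Impurity-based importances, normalized to sum 1 and sorted descending
    (ties broken by feature-column order).  Tree-based models only."""
    importances = getattr(model, "feature_importances_", None)
    if importances is None:
        raise ValueError(
            f"{type(model).__name__} exposes no impurity-based feature importances "
            "(tree-based families only)"
        )
    w = np.asarray(importances, dtype=float)
    if len(w) != len(feature_names):
        raise ValueError("feature name count does not match importance vector length")
    total = w.sum()
    w = w / total if total > 0 else np.full_like(w, 1.0 / len(w))
    order = sorted(range(len(w)), key=lambda i: (-w[i], i))
    return [(feature_names[i], float(w[i])) for i in order]


@dataclass
class ModelCVResult:
    family: str
    fold_metrics: list[Metrics | None]
    train_metrics: list[Metrics | None]
    mean: dict[str, float]
    std: dict[str, float]
    importances: list[tuple[str, float]] | None
    predictions: pd.DataFrame  # validation predictions: subject_id, fold, age, predicted
    train_pairs: list[tuple[np.ndarray, np.ndarray]]  # per fold (real, predicted) on train
    models: list
    errors: list[str]


@dataclass
class CVResult:
    fold_labels: np.ndarray
    subject_ids: list[str]
    per_model: dict[str, ModelCVResult]
    k: int
    seed: int


def _aggregate(metrics: list[Metrics | None]) -> tuple[dict, dict]:
    keys = ("r", "rmse", "mape", "r2")
    ok = [m for m in metrics if m is not None]
    if not ok:
        return {k: float("nan") for k in keys}, {k: float("nan") for k in keys}
    mean = {k: float(np.mean([getattr(m, k) for m in ok])) for k in keys}
    std = {k: float(np.std([getattr(m, k) for m in ok])) for k in keys}
    return mean, std


def run_cv(
    table: pd.DataFrame,
    specs: Sequence[ModelSpec] | None = None,
    k: int = 4,
    seed: int = 0,
    search: bool = False,
    n_iter: int = 20,
    feature_columns: Sequence[str] | None = None,
) -> CVResult:
    """k-fold cross-validation of the model specs on a modeling table.

    Per fold: (optionally) tune by randomized search on the training
    portion, fit, predict held-out and training subjects, evaluate.  A
    family failing on a fold is recorded as an error; other families
    proceed.
    """
    from .cohort import FEATURE_COLUMNS  # deferred: avoid import cycle at module load

    feats = list(feature_columns) if feature_columns is not None else list(FEATURE_COLUMNS)
    if specs is None:
        specs = default_model_specs(seed=seed)
    missing = [c for c in feats + ["age", "subject_id"] if c not in table.columns]
    if missing:
        raise ValueError(f"modeling table is missing columns: {missing}")
    ids = table["subject_id"].astype(str).tolist()
    X = table[feats].to_numpy(dtype=float)
    y = table["age"].to_numpy(dtype=float)
    folds = assign_folds(ids, k, seed=seed)

    per_model: dict[str, ModelCVResult] = {}
    for spec in specs:
        fold_metrics: list[Metrics | None] = []
        train_metrics: list[Metrics | None] = []
        rows = []
        train_pairs: list[tuple[np.ndarray, np.ndarray]] = []
        models = []
        errors: list[str] = []
        fold_importances = []
        for f in range(k):
            tr, va = folds != f, folds == f
            try:
                fit_spec = spec
                if search and spec.search_space:
                    fit_spec = randomized_search(
                        spec, X[tr], y[tr], n_iter=n_iter, seed=seed + f
                    ).spec
                est = build_estimator(fit_spec)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                y_val = np.asarray(est.predict(X[va]), dtype=float)
                y_tr = np.asarray(est.predict(X[tr]), dtype=float)
                fold_metrics.append(evaluate(y[va], y_val))
                train_metrics.append(evaluate(y[tr], y_tr))
                train_pairs.append((y[tr].copy(), y_tr))
                for idx, pred in zip(np.flatnonzero(va), y_val):
                    rows.append({"subject_id": ids[idx], "fold": f, "age": y[idx], "predicted": pred})
                models.append(est)
                if spec.family in TREE_FAMILIES:
                    fold_importances.append(dict(feature_importance(est, feats)))
            except Exception as exc:  # record and move on; other models proceed
                fold_metrics.append(None)
                train_metrics.append(None)
                train_pairs.append((np.array([]), np.array([])))
                models.append(None)
                errors.append(f"fold {f}: {type(exc).__name__}: {exc}")
        mean, std = _aggregate(fold_metrics)
        importances = None
        if fold_importances:
            avg = np.array([[fi[name] for name in feats] for fi in fold_importances]).mean(axis=0)
            total = avg.sum()
            avg = avg / total if total > 0 else np.full_like(avg, 1.0 / len(avg))
            order = sorted(range(len(avg)), key=lambda i: (-avg[i], i))
            importances = [(feats[i], float(avg[i])) for i in order]
        per_model[spec.family] = ModelCVResult(
            family=spec.family,
            fold_metrics=fold_metrics,
            train_metrics=train_metrics,
            mean=mean,
            std=std,
            importances=importances,
            predictions=pd.DataFrame(rows, columns=["subject_id", "fold", "age", "predicted"]),
            train_pairs=train_pairs,
            models=models,
            errors=errors,
        )
    return CVResult(fold_labels=folds, subject_ids=ids, per_model=per_model, k=k, seed=seed)


def metrics_frame(result: CVResult) -> pd.DataFrame:
    """Aggregated report: one row per model, 'mean ± std' per metric."""
    rows = []
    for family, res in result.per_model.items():
        rows.append(
            {
                "model": family,
                "RMSE": f"{res.mean['rmse']:.3f} ± {res.std['rmse']:.3f}",
                "R2": f"{res.mean['r2']:.3f} ± {res.std['r2']:.3f}",
                "MAPE": f"{res.mean['mape']:.3f} ± {res.std['mape']:.3f}",
                "r": f"{res.mean['r']:.3f} ± {res.std['r']:.3f}",
            }
        )
    return pd.DataFrame(rows, columns=["model", "RMSE", "R2", "MAPE", "r"])


def metrics_frame_numeric(result: CVResult) -> pd.DataFrame:
    rows = []
    for family, res in result.per_model.items():
        row = {"model": family}
        for key in ("rmse", "r2", "mape", "r"):
            row[f"{key}_mean"] = res.mean[key]
            row[f"{key}_std"] = res.std[key]
        rows.append(row)
    return pd.DataFrame(rows)


def scatter_plot(x, y, destination, title: str | None = None) -> str:
    """Scatter of real vs predicted age with the y = x identity line.

    Writes the image and a JSON sidecar with the plotted coordinates
    (destination + '.json') for programmatic verification.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be nonempty arrays of equal shape")
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, s=14, color="tab:blue", alpha=0.8)
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    pad = 0.05 * max(hi - lo, 1.0)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad], color="red", linewidth=1.0)
    ax.set_xlabel("real age (years)")
    ax.set_ylabel("predicted age (years)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(destination, dpi=110)
    plt.close(fig)
    sidecar = str(destination) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"real": x.tolist(), "predicted": y.tolist()}, fh)
    return str(destination)
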