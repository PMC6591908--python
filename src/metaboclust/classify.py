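"""Trait classifiers: single-metabolite logistic models and multi-metabolite
machine-learning models with LOOCV model selection and external validation.

The workflow mirrors biomarker practice: logistic regression per significant
metabolite; SVM, PLS-DA, random-forest and gradient-boosted-tree models on
multi-metabolite bins; a grid search over tuning parameters scored by
leave-one-out cross-validation accuracy; a probability threshold chosen from
the LOOCV ROC; a final fit on all training samples; and frozen-threshold
evaluation on an external cohort.  Thresholds and hyperparameters are
functions of the training data only.

Margin-based families (SVM, PLS-DA) yield probabilities through a logistic
link fitted to their decision values within each training fold, since
threshold selection operates on probabilities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .io import DatasetError, IntensityTable

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import ClusterAssignment
    from .diffstats import DifferentialResult

FAMILIES = ("logistic", "svm", "plsda", "random_forest", "gradient_boosted_trees")

#: Small ridge penalty (as 1/C) keeping logistic fits finite on separable data.
_LOGISTIC_RIDGE = 1e-8


def default_grid(family: str, n_features: int) -> dict[str, tuple]:
    """Default hyperparameter grids for each model family."""
    if family == "logistic":
        return {}
    if family == "svm":
        return {"cost": (0.25, 0.5, 1.0, 2.0, 4.0)}
    if family == "plsda":
        return {"n_components": tuple(range(1, min(5, n_features) + 1))}
    if family == "random_forest":
        return {"mtry": tuple(range(1, n_features + 1)), "n_trees": (500,)}
    if family == "gradient_boosted_trees":
        return {"max_depth": (1, 2, 3), "n_rounds": (50, 150), "learning_rate": (0.3,)}
    raise DatasetError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    """A model family applied to a metabolite subset with a tuning grid."""

    metabolite_set: tuple[str, ...]
    family: str
    grid: Mapping[str, tuple] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES and self.family != "majority":
            raise DatasetError(f"unknown model family {self.family!r}")
        if self.family == "logistic" and len(self.metabolite_set) != 1:
            raise DatasetError("logistic models are single-metabolite only")
        if not self.metabolite_set:
            raise DatasetError("metabolite_set must be non-empty")

    def grid_points(self) -> list[dict]:
        grid = dict(self.grid) if self.grid is not None else default_grid(
            self.family, len(self.metabolite_set)
        )
        if not grid:
            return [{}]
        keys = list(grid)
        for k in keys:
            if not grid[k]:
                raise DatasetError(f"empty grid for parameter {k!r}")
        return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


# -- model families ------------------------------------------------------------


class _PlattLink:
    """Logistic link from a 1-d decision value to a case probability."""

    def __init__(self, decision: np.ndarray, y: np.ndarray):
        self._lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
        self._lr.fit(decision.reshape(-1, 1), y)

    def __call__(self, decision: np.ndarray) -> np.ndarray:
        return self._lr.predict_proba(decision.reshape(-1, 1))[:, 1]


class _FittedModel:
    """A fitted family with a uniform predict_proba_case interface."""

    def __init__(self, family: str, predict):
        self.family = family
        self._predict = predict

    def predict_proba_case(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self._predict(np.asarray(X, float)), 0.0, 1.0)


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF kernel width from the median pairwise Euclidean distance."""
    if X.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(X)))
    return 1.0 if med == 0.0 else 1.0 / (2.0 * med**2)


def fit_family(
    family: str, params: Mapping, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> _FittedModel:
    """Fit one model family; returns an object emitting case probabilities."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if family == "majority":
        # Diagnostic dummy: constant majority-class probability, ties -> 0.
        counts = np.bincount(y, minlength=2)
        p = 1.0 if counts[1] > counts[0] else 0.0
        return _FittedModel(family, lambda Z, p=p: np.full(Z.shape[0], p))
    if len(np.unique(y)) < 2:
        raise DatasetError(f"cannot fit {family!r}: training data has a single class")
    if family == "logistic":
        lr = LogisticRegression(
            C=1.0 / _LOGISTIC_RIDGE, solver="lbfgs", max_iter=10_000
        )
        lr.fit(X, y)
        return _FittedModel(family, lambda Z: lr.predict_proba(Z)[:, 1])
    if family == "svm":
        gamma = _median_heuristic_gamma(X)
        svc = SVC(C=float(params.get("cost", 1.0)), kernel="rbf", gamma=gamma)
        svc.fit(X, y)
        link = _PlattLink(svc.decision_function(X), y)
        return _FittedModel(family, lambda Z: link(svc.decision_function(Z)))
    if family == "plsda":
        ncomp = int(params.get("n_components", 1))
        ncomp = min(ncomp, X.shape[1], X.shape[0] - 1)
        pls = PLSRegression(n_components=max(ncomp, 1), scale=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-column scaling warnings
            pls.fit(X, y.astype(float))
            link = _PlattLink(pls.predict(X).ravel(), y)
            return _FittedModel(family, lambda Z: link(pls.predict(Z).ravel()))
    if family == "random_forest":
        mtry = int(params.get("mtry", max(1, int(np.sqrt(X.shape[1])))))
        rf = RandomForestClassifier(
            n_estimators=int(params.get("n_trees", 500)),
            max_features=min(mtry, X.shape[1]),
            random_state=seed,
            n_jobs=1,
        )
        rf.fit(X, y)
        return _FittedModel(family, lambda Z: rf.predict_proba(Z)[:, 1])
    if family == "gradient_boosted_trees":
        xgb = XGBClassifier(
            max_depth=int(params.get("max_depth", 3)),
            n_estimators=int(params.get("n_rounds", 50)),
            learning_rate=float(params.get("learning_rate", 0.3)),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
            tree_method="exact",
        )
        xgb.fit(X, y)
        return _FittedModel(family, lambda Z: xgb.predict_proba(Z)[:, 1])
    raise DatasetError(f"unknown model family {family!r}")


# -- LOOCV and threshold selection ---------------------------------------------


def _design(table: IntensityTable, metabolite_set: Sequence[str]) -> np.ndarray:
    missing = [m for m in metabolite_set if m not in table.values.columns]
    if missing:
        raise DatasetError(f"metabolite(s) absent from table: {missing}")
    return table.values.loc[:, list(metabolite_set)].to_numpy(float)


def loocv_probabilities(
    table: IntensityTable, spec: ClassifierSpec, params: Mapping | None = None
) -> np.ndarray:
    """Out-of-fold case probabilities: sample i predicted by a fit on all others."""
    params = dict(params or {})
    X = _design(table, spec.metabolite_set)
    y = table.labels01()
    if spec.family != "majority" and min(np.bincount(y, minlength=2)) < 2:
        raise DatasetError("LOOCV requires at least 2 samples per class")
    n = X.shape[0]
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        model = fit_family(spec.family, params, X[mask], y[mask], seed=spec.seed)
        probs[i] = model.predict_proba_case(X[i : i + 1])[0]
    return probs


def _metrics_at(probs: np.ndarray, y: np.ndarray, threshold: float) -> tuple[float, float, float]:
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / y.size
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return acc, sens, spec


def rank_auc(probs: Sequence[float], y: Sequence[int]) -> float:
    """AUC by the Mann-Whitney rank statistic with ties counted half."""
    probs = np.asarray(probs, float)
    y = np.asarray(y, int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise DatasetError("AUC requires both classes")
    from scipy.stats import rankdata

    ranks = rankdata(probs)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float

    def metrics(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def select_threshold(probs: Sequence[float], labels: Sequence[int]) -> ThresholdResult:
    """Probability cutoff maximizing accuracy on the given predictions.

    Candidates are midpoints of adjacent sorted unique probabilities plus
    guards toward 0 and 1 (so both constant classifiers are available).
    Ties go to the highest specificity, then to the lowest threshold.
    Prediction rule: case iff probability >= threshold.
    """
    probs = np.asarray(probs, float)
    y = np.asarray(labels, int)
    if probs.shape != y.shape:
        raise DatasetError("probabilities and labels must have the same length")
    if len(np.unique(y)) < 2:
        raise DatasetError("threshold selection requires both classes")
    uniq = np.unique(probs)
    cands = [(0.0 + uniq[0]) / 2.0]
    cands += [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])]
    cands += [(uniq[-1] + 1.0) / 2.0]
    cands = [min(max(c, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0)) for c in cands]
    best: tuple[float, float, float] | None = None  # (-acc, -spec, threshold)
    best_at: tuple[float, float, float] | None = None
    for t in cands:
        acc, sens, spec = _metrics_at(probs, y, t)
        key = (-acc, -spec, t)
        if best is None or key < best:
            best = key
            best_at = (t, acc, sens)
            best_spec = spec
    t, acc, sens = best_at  # type: ignore[misc]
    return ThresholdResult(
        threshold=t, accuracy=acc, sensitivity=sens, specificity=best_spec,
        auc=rank_auc(probs, y),
    )


# -- grid search, final fit, external validation -------------------------------


@dataclass
class ClassifierReport:
    """Everything recorded about one trained classifier."""

    name: str
    spec: ClassifierSpec
    chosen_hyperparameters: dict
    threshold: float
    internal: dict[str, float]
    external: dict[str, float] | None = None
    model: _FittedModel | None = None
    internal_probabilities: np.ndarray | None = None

    def summary_row(self) -> dict:
        row = {
            "model": self.name,
            "family": self.spec.family,
            "metabolites": ";".join(self.spec.metabolite_set),
            "n_metabolites": len(self.spec.metabolite_set),
            "hyperparameters": repr(self.chosen_hyperparameters),
            "threshold": self.threshold,
        }
        for k, v in self.internal.items():
            row[f"internal_{k}"] = v
        for k in ("accuracy", "sensitivity", "specificity", "auc"):
            row[f"external_{k}"] = self.external.get(k) if self.external else np.nan
        return row


def grid_search(
    table: IntensityTable, spec: ClassifierSpec, *, name: str | None = None
) -> ClassifierReport:
    """LOOCV every grid point; keep the first point with maximal LOOCV accuracy."""
    best: tuple[float, int] | None = None
    best_params: dict = {}
    best_probs: np.ndarray | None = None
    best_thr: ThresholdResult | None = None
    for gi, params in enumerate(spec.grid_points()):
        probs = loocv_probabilities(table, spec, params)
        thr = select_threshold(probs, table.labels01())
        key = (-thr.accuracy, gi)
        if best is None or key < best:
            best, best_params, best_probs, best_thr = key, params, probs, thr
    assert best_thr is not None and best_probs is not None
    return ClassifierReport(
        name=name or f"{spec.family}:{'+'.join(spec.metabolite_set)}",
        spec=spec,
        chosen_hyperparameters=best_params,
        threshold=best_thr.threshold,
        internal=best_thr.metrics(),
        internal_probabilities=best_probs,
    )


def train_final(
    table: IntensityTable, spec: ClassifierSpec, params: Mapping
) -> _FittedModel:
    """Single fit on all training samples with the LOOCV-chosen parameters."""
    X = _design(table, spec.metabolite_set)
    return fit_family(spec.family, params, X, table.labels01(), seed=spec.seed)


def external_validate(
    model: _FittedModel,
    threshold: float,
    test_table: IntensityTable,
    metabolite_set: Sequence[str],
) -> dict[str, float]:
    """Frozen-threshold metrics on an independently preprocessed cohort."""
    X = _design(test_table, metabolite_set)
    y = test_table.labels01()
    probs = model.predict_proba_case(X)
    acc, sens, spec = _metrics_at(probs, y, threshold)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "auc": rank_auc(probs, y),
    }


# -- the model suite -----------------------------------------------------------

DEFAULT_ML_FAMILIES = ("svm", "plsda", "random_forest", "gradient_boosted_trees")


def build_model_suite(
    table: IntensityTable,
    diff: "DifferentialResult",
    clusters: "ClusterAssignment",
    *,
    families: Sequence[str] = DEFAULT_ML_FAMILIES,
    seed: int = 0,
    grids: Mapping[str, Mapping] | None = None,
    fit_final: bool = True,
) -> list[ClassifierReport]:
    """The full comparison suite.

    One logistic model per significant metabolite; each ML family on each
    multi-member cluster of significant metabolites; and each ML family on
    the all-metabolite and all-significant baselines.  Every entry is tuned
    by :func:`grid_search`; ``fit_final`` attaches the model refitted on all
    training samples.
    """
    sig = [m for m in table.metabolites if m in set(diff.significant_ids)]
    reports: list[ClassifierReport] = []

    def _run(name: str, metabolite_set: Sequence[str], family: str) -> None:
        grid = dict(grids[family]) if grids and family in grids else None
        spec = ClassifierSpec(tuple(metabolite_set), family, grid=grid, seed=seed)
        rep = grid_search(table, spec, name=name)
        if fit_final:
            rep.model = train_final(table, spec, rep.chosen_hyperparameters)
        reports.append(rep)

    if not sig:
        warnings.warn("no significant metabolites; suite contains only all-metabolite models")
    for m in sig:
        _run(f"single:{m}", [m], "logistic")
    for lab, members in clusters.multi_member_clusters().items():
        members = [m for m in members if m in set(sig)]
        if len(members) < 2:
            continue
        for fam in families:
            _run(f"cluster{lab}:{fam}", members, fam)
    for fam in families:
        _run(f"all:{fam}", table.metabolites, fam)
    if sig:
        for fam in families:
            _run(f"significant:{fam}", sig, fam)
    return reports


def validate_suite(
    reports: Sequence[ClassifierReport], test_table: IntensityTable
) -> None:
    """Attach external metrics to every report holding a fitted model."""
    for rep in reports:
        if rep.model is None:
            raise DatasetError(f"report {rep.name!r} has no fitted model")
        rep.external = external_validate(
            rep.model, rep.threshold, test_table, rep.spec.metabolite_set
        )


def select_best(reports: Sequence[ClassifierReport]) -> ClassifierReport:
    """Best report by internal LOOCV accuracy.

    Ties go to the higher internal AUC, then the smaller metabolite set.
    External metrics are never consulted.
    """
    if not reports:
        raise DatasetError("empty report list")
    return min(
        reports,
        key=lambda r: (
            -r.internal["accuracy"],
            -r.internal["auc"],
            len(r.spec.metabolite_set),
        ),
    )


def suite_frame(reports: Sequence[ClassifierReport]) -> pd.DataFrame:
    return pd.DataFrame([r.summary_row() for r in reports])
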