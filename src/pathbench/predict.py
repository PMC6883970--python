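"""Pathway-activity prediction tasks under repeated nested cross-validation.

Three tasks consume a sample-by-pathway activity matrix: elastic-net
logistic regression for a binary phenotype (AUC / area under the
precision-recall curve), a linear one-vs-one SVM for subtypes (accuracy,
macro precision/recall), and an elastic-net Cox proportional-hazards
model for right-censored survival (Harrell's c-index).  All tasks share
the same design: an outer repeated stratified k-fold loop scores
held-out folds only, while hyperparameters are tuned by an inner
cross-validation on the training folds, and feature standardization is
fitted on training folds only — no information from a held-out fold ever
reaches model fitting.

Database impact on the per-fold metrics is then assessed with a two-way
ANOVA (performance ~ database + dataset + database:dataset, F-test on the
database factor) and pairwise rank-sum tests with Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedStratifiedKFold,
    StratifiedKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .ora import adjust

logger = logging.getLogger(__name__)

#: Elastic-net mixing grid (l1 fraction) shared by logistic and Cox tasks.
L1_RATIO_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
#: Inverse regularization strengths for the logistic task.
C_GRID = tuple(np.logspace(-2, 2, 5))
#: Soft-margin grid for the linear SVM.
SVM_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
#: Regularization strengths for the penalized Cox model.
COX_ALPHA_GRID = tuple(np.logspace(-3, 0, 5))


def outer_splits(stratify_on, repeats: int, folds: int, seed=None):
    """Repeated stratified outer folds as (repeat, fold, train_idx, test_idx)."""
    y = np.asarray(stratify_on)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    out = []
    for i, (train, test) in enumerate(cv.split(np.zeros(len(y)), y)):
        out.append((i // folds, i % folds, train, test))
    return out


def binary_cv(
    activity: pd.DataFrame,
    labels,
    repeats: int = 10,
    folds: int = 10,
    l1_ratio_grid=L1_RATIO_GRID,
    c_grid=C_GRID,
    inner_folds: int = 5,
    seed: int | None = None,
    splits=None,
) -> pd.DataFrame:
    """Nested-CV evaluation of an elastic-net logistic classifier.

    ``activity`` is samples x pathways; ``labels`` a binary vector aligned
    to its rows.  Returns one row per evaluable outer fold with ``auc``,
    ``auprc`` and the inner-CV-selected hyperparameters.
    """
    X = activity.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary task requires 2 classes, got {len(classes)}")
    if splits is None:
        splits = outer_splits(y, repeats, folds, seed)

    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("model", LogisticRegression(solver="saga", max_iter=5000, tol=1e-3)),
    ])
    grid = {
        "model__l1_ratio": list(l1_ratio_grid),
        "model__C": list(c_grid),
    }
    rows = []
    for repeat, fold, train, test in splits:
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            logger.warning("repeat %d fold %d degenerate (single class); skipped", repeat, fold)
            continue
        search = GridSearchCV(
            pipe, grid, scoring="roc_auc",
            cv=StratifiedKFold(inner_folds, shuffle=True, random_state=seed),
        )
        search.fit(X[train], y[train])
        scores = search.decision_function(X[test])
        y_test = (y[test] == classes[1]).astype(int)
        rows.append({
            "task": "binary",
            "repeat": repeat,
            "fold": fold,
            "auc": roc_auc_score(y_test, scores),
            "auprc": average_precision_score(y_test, scores),
            "l1_ratio": search.best_params_["model__l1_ratio"],
            "C": search.best_params_["model__C"],
        })
    return pd.DataFrame(rows)


def subtype_cv(
    activity: pd.DataFrame,
    labels,
    repeats: int = 10,
    folds: int = 10,
    c_grid=SVM_C_GRID,
    inner_folds: int = 5,
    seed: int | None = None,
    splits=None,
) -> pd.DataFrame:
    """Nested-CV evaluation of a linear one-vs-one SVM subtype classifier.

    Reports accuracy and macro-averaged precision/recall per outer fold.
    Every class must have at least ``folds`` members for stratification.
    """
    X = activity.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("subtype task requires at least 2 classes")
    for cls, count in zip(classes, counts):
        if count < folds:
            raise ValueError(
                f"class {cls!r} has {count} members; cannot stratify into {folds} folds"
            )
    if splits is None:
        splits = outer_splits(y, repeats, folds, seed)

    # SVC fits one classifier per class pair (one-vs-one) natively
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("model", SVC(kernel="linear", decision_function_shape="ovo")),
    ])
    rows = []
    for repeat, fold, train, test in splits:
        search = GridSearchCV(
            pipe, {"model__C": list(c_grid)}, scoring="accuracy",
            cv=StratifiedKFold(inner_folds, shuffle=True, random_state=seed),
        )
        search.fit(X[train], y[train])
        predicted = search.predict(X[test])
        rows.append({
            "task": "subtype",
            "repeat": repeat,
            "fold": fold,
            "accuracy": accuracy_score(y[test], predicted),
            "precision": precision_score(y[test], predicted, average="macro", zero_division=0),
            "recall": recall_score(y[test], predicted, average="macro", zero_division=0),
            "C": search.best_params_["model__C"],
        })
    return pd.DataFrame(rows)


def concordance_index(risk, time, event) -> float:
    """Harrell's concordance index by all-pairs counting.

    A pair is comparable when the earlier time carries an observed event
    (equal times are not comparable).  Concordant means the
    earlier-failing sample has the higher risk; risk ties count 0.5.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    earlier = (time[:, None] < time[None, :]) & event[:, None]
    n_comparable = int(earlier.sum())
    if n_comparable == 0:
        raise ValueError("no comparable pair (need an observed event before another time)")
    concordant = int((earlier & (risk[:, None] > risk[None, :])).sum())
    tied = int((earlier & (risk[:, None] == risk[None, :])).sum())
    return (concordant + 0.5 * tied) / n_comparable


def survival_cv(
    activity: pd.DataFrame,
    survival: pd.DataFrame,
    repeats: int = 10,
    folds: int = 10,
    l1_ratio_grid=L1_RATIO_GRID,
    alpha_grid=COX_ALPHA_GRID,
    inner_folds: int = 5,
    seed: int | None = None,
    splits=None,
) -> pd.DataFrame:
    """Nested-CV evaluation of an elastic-net Cox proportional-hazards model.

    ``survival`` needs ``time`` (positive) and ``event`` (1 = death
    observed) columns aligned to the activity rows.  Outer folds are
    stratified on the event flag so every training fold retains events;
    folds that end up without events or without comparable pairs are
    skipped with a warning.  Reports the held-out c-index per fold.
    """
    X = activity.to_numpy(dtype=float)
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy().astype(bool)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if splits is None:
        splits = outer_splits(event.astype(int), repeats, folds, seed)

    rows = []
    for repeat, fold, train, test in splits:
        if event[train].sum() < 2:
            logger.warning("repeat %d fold %d has <2 training events; skipped", repeat, fold)
            continue
        scaler = StandardScaler().fit(X[train])
        X_train, X_test = scaler.transform(X[train]), scaler.transform(X[test])
        best, best_score = None, -np.inf
        inner = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
        inner_sets = list(inner.split(X_train, event[train].astype(int)))
        for l1_ratio, alpha in itertools.product(l1_ratio_grid, alpha_grid):
            scores = []
            for in_train, in_val in inner_sets:
                if event[train][in_train].sum() < 2:
                    continue
                model = _fit_coxnet(X_train[in_train], time[train][in_train],
                                    event[train][in_train], l1_ratio, alpha)
                if model is None:
                    continue
                try:
                    scores.append(concordance_index(
                        model.predict(X_train[in_val]),
                        time[train][in_val], event[train][in_val],
                    ))
                except ValueError:
                    continue
            if scores and np.mean(scores) > best_score:
                best, best_score = (l1_ratio, alpha), float(np.mean(scores))
        if best is None:
            logger.warning("repeat %d fold %d: no tunable model; skipped", repeat, fold)
            continue
        model = _fit_coxnet(X_train, time[train], event[train], *best)
        if model is None:
            logger.warning("repeat %d fold %d: final fit failed; skipped", repeat, fold)
            continue
        try:
            c_index = concordance_index(model.predict(X_test), time[test], event[test])
        except ValueError:
            logger.warning("repeat %d fold %d: no comparable test pair; skipped", repeat, fold)
            continue
        rows.append({
            "task": "survival",
            "repeat": repeat,
            "fold": fold,
            "c_index": c_index,
            "l1_ratio": best[0],
            "alpha": best[1],
        })
    return pd.DataFrame(rows)


def _fit_coxnet(X, time, event, l1_ratio, alpha):
    model = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, alphas=[alpha], fit_baseline_model=False, max_iter=100000
    )
    try:
        with warnings.catch_warnings():
            # the top of the penalty grid legitimately shrinks all
            # coefficients to zero; that fit scores poorly and is discarded
            warnings.filterwarnings("ignore", message="all coefficients are zero")
            model.fit(X, Surv.from_arrays(event, time))
    except (ValueError, ArithmeticError):
        return None
    return model


def performance_anova(table: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Two-way ANOVA of fold metrics: performance ~ database * dataset.

    Requires >=2 databases, >=2 datasets and >=2 replicates per cell.
    Returns (F, p) for the database main effect and the full decomposition
    (including residuals).
    """
    for column in ("performance", "database", "dataset"):
        if column not in table.columns:
            raise ValueError(f"missing column {column!r}")
    for factor in ("database", "dataset"):
        if table[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has a single level")
    cells = table.groupby(["database", "dataset"], sort=True).size()
    expected = table["database"].nunique() * table["dataset"].nunique()
    if len(cells) < expected:
        present = set(cells.index)
        missing = [
            (db, ds)
            for db in sorted(table["database"].unique())
            for ds in sorted(table["dataset"].unique())
            if (db, ds) not in present
        ]
        raise ValueError(f"empty design cell(s): {missing}")
    if (cells < 2).any():
        raise ValueError(f"design cells with <2 replicates: {cells[cells < 2].index.tolist()}")
    if np.var(table["performance"].to_numpy()) < 1e-24:
        # a constant response carries no information and the F statistic
        # would be pure round-off noise
        raise ValueError("performance values are constant; no variance to decompose")
    model = smf.ols("performance ~ C(database) * C(dataset)", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    f_db = float(anova.loc["C(database)", "F"])
    p_db = float(anova.loc["C(database)", "PR(>F)"])
    return f_db, p_db, anova


def pairwise_wilcoxon_bh(perf_by_database: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise rank-sum tests between databases with BH correction.

    Metric vectors are unpaired (fold compositions differ per database),
    so the Mann-Whitney rank-sum form is used.  Pairs where either vector
    has fewer than 3 values are skipped with a warning.
    """
    if len(perf_by_database) < 2:
        raise ValueError("need at least 2 databases to compare")
    rows = []
    for db_a, db_b in itertools.combinations(sorted(perf_by_database), 2):
        a = np.asarray(perf_by_database[db_a], dtype=float)
        b = np.asarray(perf_by_database[db_b], dtype=float)
        if len(a) < 3 or len(b) < 3:
            logger.warning("pair (%s, %s) skipped: fewer than 3 values", db_a, db_b)
            continue
        _, p = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        rows.append({"database_a": db_a, "database_b": db_b, "p_value": float(min(p, 1.0))})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["q_value"] = adjust(frame["p_value"].to_numpy(), method="bh")
    return frame
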