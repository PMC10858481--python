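"""Split protocols, per-metabolite rank-correlation scoring, host-condition
prediction, and between-model significance tests.

The protocol throughout is 80/20 train/test splits repeated 10 times;
metrics are computed per repeat and then averaged (standard errors over
repeats).  Binary conditions use L2-regularized logistic regression with
the fixed inverse-strength C=1 and AUC; continuous conditions use Ridge
regression at its default strength and the Spearman correlation.  No
hyperparameter tuning anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import roc_auc_score

STAR_THRESHOLDS_4 = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))
STAR_THRESHOLDS_3 = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class SplitPlan:
    """Reproducible list of (train, test) index pairs."""

    n_samples: int
    test_fraction: float
    n_repeats: int
    seed: int
    splits: list = field(default_factory=list)


def make_splits(n: int, test_fraction: float = 0.2, n_repeats: int = 10,
                seed: int = 0) -> SplitPlan:
    """``n_repeats`` independent uniformly random train/test partitions."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 samples")
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    splits = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[n_test:]), np.sort(perm[:n_test])))
    return SplitPlan(n_samples=n, test_fraction=test_fraction,
                     n_repeats=n_repeats, seed=seed, splits=splits)


@dataclass
class MetabolitePredictionReport:
    """Per-metabolite Spearman correlations, optionally over repeats."""

    scc: np.ndarray  # (n_repeats, n_metabolites) or (n_metabolites,)
    model_tag: str = ""
    constant_columns: list = field(default_factory=list)

    @property
    def per_metabolite(self) -> np.ndarray:
        return np.atleast_2d(self.scc).mean(axis=0)

    @property
    def mean(self) -> float:
        return float(np.atleast_2d(self.scc).mean())

    @property
    def sem(self) -> float:
        flat = np.atleast_2d(self.scc).ravel()
        return float(flat.std(ddof=1) / np.sqrt(flat.size)) if flat.size > 1 else 0.0


def score_metabolites(Me_true, Me_pred, model_tag: str = "",
                      ) -> MetabolitePredictionReport:
    """Spearman correlation per metabolite (average-rank tie handling).

    A constant true or predicted column yields SCC 0 and is flagged.
    """
    T = Me_true.to_numpy(dtype=float) if isinstance(Me_true, pd.DataFrame) \
        else np.asarray(Me_true, dtype=float)
    P = Me_pred.to_numpy(dtype=float) if isinstance(Me_pred, pd.DataFrame) \
        else np.asarray(Me_pred, dtype=float)
    if T.shape != P.shape:
        raise ValueError(f"shape mismatch: {T.shape} vs {P.shape}")
    cols = (list(Me_true.columns) if isinstance(Me_true, pd.DataFrame)
            else list(range(T.shape[1])))
    sccs = np.zeros(T.shape[1])
    constant = []
    for j in range(T.shape[1]):
        if np.ptp(T[:, j]) == 0 or np.ptp(P[:, j]) == 0:
            sccs[j] = 0.0
            constant.append(cols[j])
            continue
        sccs[j] = stats.spearmanr(T[:, j], P[:, j]).statistic
    return MetabolitePredictionReport(scc=sccs, model_tag=model_tag,
                                      constant_columns=constant)


@dataclass
class ConditionPredictionReport:
    """Per-repeat condition-prediction metric (AUC or SCC)."""

    task: str  # "binary" or "continuous"
    per_repeat: np.ndarray
    feature_tag: str = ""
    skipped_repeats: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repeat)) if len(self.per_repeat) else float("nan")

    @property
    def sem(self) -> float:
        v = np.asarray(self.per_repeat)
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0


def predict_condition(features, labels, task: str, splits: SplitPlan,
                      feature_tag: str = "") -> ConditionPredictionReport:
    """Condition prediction from any feature source over a split plan.

    ``task='binary'``: logistic regression (L2, C=1), AUC per repeat;
    ``task='continuous'``: Ridge (alpha=1), Spearman correlation per
    repeat.  Repeats whose training labels are single-class are skipped
    with a warning and counted.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    if task not in {"binary", "continuous"}:
        raise ValueError("task must be 'binary' or 'continuous'")
    vals = []
    skipped = 0
    for train, test in splits.splits:
        if task == "binary":
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                skipped += 1
                continue
            clf = LogisticRegression(C=1.0, max_iter=2000)
            clf.fit(X[train], y[train])
            scores = clf.decision_function(X[test])
            vals.append(roc_auc_score(y[test], scores))
        else:
            reg = Ridge(alpha=1.0)
            reg.fit(X[train], y[train].astype(float))
            pred = reg.predict(X[test])
            if np.ptp(pred) == 0 or np.ptp(y[test]) == 0:
                vals.append(0.0)
            else:
                vals.append(stats.spearmanr(y[test], pred).statistic)
    if skipped:
        warnings.warn(f"{skipped} repeats skipped (single-class training split)")
    return ConditionPredictionReport(task=task, per_repeat=np.asarray(vals),
                                     feature_tag=feature_tag,
                                     skipped_repeats=skipped)


def star_code(p: float, tiers: int = 4) -> str:
    """Significance stars: * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001
    (``tiers=3`` drops the **** tier)."""
    table = STAR_THRESHOLDS_4 if tiers == 4 else STAR_THRESHOLDS_3
    for threshold, code in table:
        if p <= threshold:
            return code
    return "ns"


def compare_models(scores_a, scores_b, sided: str = "two-sided",
                   tiers: int = 4) -> dict:
    """Welch t-test between two score vectors with a star code.

    ``sided='greater'`` tests mean(a) > mean(b).  Degenerate zero-variance
    inputs are handled with a small variance floor so that identical
    vectors give p=1 and a constant shift gives p -> 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 scores per group")
    if sided not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {sided!r}")
    floor = 1e-12 * max(1.0, abs(a.mean()), abs(b.mean()))
    if a.std(ddof=1) < floor and b.std(ddof=1) < floor:
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t = np.inf * np.sign(a.mean() - b.mean())
            if sided == "two-sided":
                p = 0.0
            elif sided == "greater":
                p = 0.0 if a.mean() > b.mean() else 1.0
            else:
                p = 0.0 if a.mean() < b.mean() else 1.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False, alternative=sided)
        t, p = float(res.statistic), float(res.pvalue)
    return {"t": t, "p": p, "stars": star_code(p, tiers),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "sided": sided}
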