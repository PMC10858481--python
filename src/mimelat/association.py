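"""Canonical correlation between omics views and host metadata.

Each feature source (microbiome ``Mi``, metabolome ``Me``, or the latent
representation ``Z``) is related to the per-sample metadata with CCA:
per split, the CCA is fit on the training samples and the held-out
canonical variates of the first pair are correlated (Spearman); the
metadata-side weights of the first two components identify which
covariates carry the association.  Metadata is standardized and
categorical columns are one-hot encoded; constant columns are dropped
with a warning.  The CCA itself is solved in closed form through the SVD
of the ridge-whitened cross-covariance, which is deterministic and
column-order equivariant.  A Ridge model predicting each continuous covariate from
the feature source gives a per-covariate view of the same association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge, LogisticRegression
from sklearn.metrics import roc_auc_score

from .evaluation import SplitPlan


def encode_metadata(metadata: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """One-hot encode categorical columns and drop constant columns.

    Returns the numeric design matrix and a map from encoded column ->
    source covariate (used to stack per-level weights in reports).
    """
    pieces = []
    mapping: dict[str, str] = {}
    for col in metadata.columns:
        s = metadata[col]
        if pd.api.types.is_numeric_dtype(s):
            pieces.append(s.astype(float).to_frame(col))
            mapping[col] = col
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=col,
                                     dtype=float)
            pieces.append(dummies)
            for c in dummies.columns:
                mapping[c] = col
    design = pd.concat(pieces, axis=1)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant metadata columns: {constant}")
        design = design.drop(columns=constant)
        mapping = {c: v for c, v in mapping.items() if c not in constant}
    if design.shape[1] == 0:
        raise ValueError("metadata has no informative columns")
    return design, mapping


def _standardize(train: np.ndarray, test: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    if test is None:
        return (train - mu) / sd
    return (train - mu) / sd, (test - mu) / sd


def _inv_sqrt(S: np.ndarray, ridge: float) -> np.ndarray:
    evals, evecs = np.linalg.eigh(S + ridge * np.eye(S.shape[0]))
    evals = np.maximum(evals, ridge)
    return evecs @ np.diag(evals ** -0.5) @ evecs.T


def _cca_fit(X: np.ndarray, Y: np.ndarray, n_components: int,
             ridge: float = 1e-6):
    """Covariance-whitening CCA.

    Solves the canonical problem through the SVD of the whitened
    cross-covariance ``Sxx^{-1/2} Sxy Syy^{-1/2}``; the small ridge on the
    covariance inverses keeps rank-deficient metadata well-posed.  The
    solution is deterministic and exactly equivariant under column
    permutations.  Returns ``(x_weights, y_weights, correlations)``; each
    component's sign is fixed so its largest-magnitude metadata weight is
    positive.
    """
    n = X.shape[0]
    Sxx = X.T @ X / n
    Syy = Y.T @ Y / n
    Sxy = X.T @ Y / n
    Wx = _inv_sqrt(Sxx, ridge)
    Wy = _inv_sqrt(Syy, ridge)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    k = min(n_components, s.shape[0])
    x_w = Wx @ U[:, :k]
    y_w = Wy @ Vt[:k].T
    for j in range(k):
        if y_w[np.argmax(np.abs(y_w[:, j])), j] < 0:
            y_w[:, j] = -y_w[:, j]
            x_w[:, j] = -x_w[:, j]
    return x_w, y_w, s[:k]


@dataclass
class CCAReport:
    """Held-out first-canonical-pair correlations for one feature source."""

    feature_tag: str
    per_repeat: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repeat))

    @property
    def sem(self) -> float:
        v = self.per_repeat
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0


def cca_association(X, metadata: pd.DataFrame, splits: SplitPlan,
                    feature_tag: str = "") -> CCAReport:
    """Mean held-out Spearman correlation of the first canonical pair.

    Per split: fit a one-component CCA on the training samples (internally
    standardized), project the held-out samples on both sides, and
    correlate the paired first canonical variates.
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
        else np.asarray(X, dtype=float)
    design, _ = encode_metadata(metadata)
    Y = design.to_numpy(dtype=float)
    if Xa.shape[0] != Y.shape[0]:
        raise ValueError("X and metadata must align on samples")
    vals = []
    for train, test in splits.splits:
        Xtr, Xte = _standardize(Xa[train], Xa[test])
        Ytr, Yte = _standardize(Y[train], Y[test])
        if Ytr.shape[1] == 1:
            # degenerate metadata: first canonical variate on the X side is
            # the best linear correlate of the single covariate (ridge fit)
            reg = Ridge(alpha=1e-6).fit(Xtr, Ytr[:, 0])
            u, v = reg.predict(Xte), Yte[:, 0]
        else:
            x_w, y_w, _ = _cca_fit(Xtr, Ytr, n_components=1)
            u, v = Xte @ x_w[:, 0], Yte @ y_w[:, 0]
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            vals.append(0.0)
        else:
            vals.append(stats.spearmanr(u, v).statistic)
    return CCAReport(feature_tag=feature_tag, per_repeat=np.asarray(vals))


def cca_weights(X, metadata: pd.DataFrame, n_components: int = 2,
                ) -> pd.DataFrame:
    """Absolute metadata-side weights of the first two canonical components.

    Fit on all samples.  Rows are encoded metadata columns (categorical
    covariates appear once per level, with a ``covariate`` column for
    stacking); one column per component.  If the metadata supports only
    one component, only that one is returned (flagged by the column set).
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
        else np.asarray(X, dtype=float)
    design, mapping = encode_metadata(metadata)
    Y = design.to_numpy(dtype=float)
    k = min(n_components, Y.shape[1], Xa.shape[1])
    if k < n_components:
        warnings.warn(f"only {k} canonical component(s) available")
    Xs = _standardize(Xa)
    Ys = _standardize(Y)
    _, y_w, _ = _cca_fit(Xs, Ys, n_components=k)
    W = np.abs(y_w)
    out = pd.DataFrame(W, index=design.columns,
                       columns=[f"component_{i + 1}" for i in range(k)])
    out.insert(0, "covariate", [mapping[c] for c in design.columns])
    return out


def predict_metadata(X, metadata: pd.DataFrame, splits: SplitPlan,
                     ) -> pd.DataFrame:
    """Ridge prediction of each covariate from the feature source.

    Continuous covariates are scored by held-out Spearman correlation;
    covariates with fewer than 3 distinct values are treated as binary and
    scored by AUC with logistic regression (flagged in the ``metric``
    column).  Returns one row per covariate with mean and standard error
    over the splits.
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
        else np.asarray(X, dtype=float)
    rows = []
    for col in metadata.columns:
        s = metadata[col]
        if not pd.api.types.is_numeric_dtype(s):
            codes = s.astype("category").cat.codes.to_numpy().astype(float)
        else:
            codes = s.to_numpy(dtype=float)
        binary = len(np.unique(codes)) < 3
        vals = []
        for train, test in splits.splits:
            Xtr, Xte = _standardize(Xa[train], Xa[test])
            if binary:
                if len(np.unique(codes[train])) < 2 or len(np.unique(codes[test])) < 2:
                    continue
                clf = LogisticRegression(C=1.0, max_iter=2000)
                clf.fit(Xtr, codes[train])
                vals.append(roc_auc_score(codes[test],
                                          clf.decision_function(Xte)))
            else:
                reg = Ridge(alpha=1.0).fit(Xtr, codes[train])
                pred = reg.predict(Xte)
                if np.ptp(pred) == 0 or np.ptp(codes[test]) == 0:
                    vals.append(0.0)
                else:
                    vals.append(stats.spearmanr(codes[test], pred).statistic)
        v = np.asarray(vals)
        rows.append({
            "covariate": col,
            "metric": "auc" if binary else "scc",
            "mean": float(v.mean()) if v.size else float("nan"),
            "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
            "n_repeats": int(v.size),
        })
    return pd.DataFrame(rows).set_index("covariate")
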