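"""Preprocessing chains for abundance and concentration tables.

Two chains are used throughout the package:

* microbiome: taxonomy aggregation (mean or group-wise sub-PCA) ->
  ``log10(x + eps)`` -> per-feature z-score;
* metabolome: per-sample relative normalization -> ``log10(x + eps)`` ->
  per-metabolite z-score.

The pseudocount defaults to ``eps = 0.1`` so that a zero maps to -1, a
relative frequency of 0.9 maps to 0 and 9.9 maps to 1 on the log10 scale.
Relative normalization supports both axes: per-sample (rows sum to one,
the compositional convention used for metabolite concentrations) and
per-taxon (each taxon divided by its total across samples, used by the
non-negative factorization pre-analysis).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .tables import AbundanceTable, MetaboliteTable
from .taxonomy import RANKS

DEFAULT_LOG_EPSILON = 0.1


@dataclass
class PreprocessConfig:
    """Options of the standard preprocessing chains."""

    taxonomy_level: str = "order"
    merge_method: str = "sub-pca"  # or "mean"
    log_epsilon: float = DEFAULT_LOG_EPSILON
    zscore: bool = True
    relative_axis: str = "sample-wise"  # or "taxon-wise"

    def __post_init__(self) -> None:
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be > 0")
        if self.taxonomy_level not in RANKS:
            raise ValueError(f"unknown taxonomy level {self.taxonomy_level!r}")
        if self.merge_method not in {"mean", "sub-pca"}:
            raise ValueError(f"unknown merge method {self.merge_method!r}")
        if self.relative_axis not in {"sample-wise", "taxon-wise"}:
            raise ValueError(f"unknown relative axis {self.relative_axis!r}")


def normalize_relative(table, axis: str = "sample-wise"):
    """Divide by row sums (sample-wise) or column sums (taxon-wise).

    All-zero rows/columns are left as zeros with a warning rather than
    producing NaNs.  The result carries ``state='relative'``.
    """
    if table.state not in {"raw", "merged"}:
        raise ValueError(f"expected raw values, got state={table.state!r}")
    df = table.df.astype(float)
    if axis == "sample-wise":
        sums = df.sum(axis=1)
        zero = sums == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero sample rows left as zeros")
        out = df.div(sums.where(~zero, 1.0), axis=0)
    elif axis == "taxon-wise":
        sums = df.sum(axis=0)
        zero = sums == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero feature columns left as zeros")
        out = df.div(sums.where(~zero, 1.0), axis=1)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return table.with_values(out, state="relative")


def normalize_log(table, epsilon: float = DEFAULT_LOG_EPSILON):
    """Elementwise ``x -> log10(x + epsilon)``; requires ``epsilon > 0``."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    values = table.df.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("log normalization expects non-negative values")
    out = pd.DataFrame(np.log10(values + epsilon),
                       index=table.df.index, columns=table.df.columns)
    return table.with_values(out, state="log")


@dataclass
class ZScaler:
    """Per-feature standardizer with population (ddof=0) statistics.

    Statistics are estimated once on the training table and reused on any
    later table so held-out samples never leak into the normalization.
    Zero-variance features get std replaced by 1 and are flagged.
    """

    mean: pd.Series
    std: pd.Series
    constant_features: list = field(default_factory=list)

    @classmethod
    def fit(cls, table) -> "ZScaler":
        df = table.df
        mean = df.mean(axis=0)
        std = df.std(axis=0, ddof=0)
        constant = list(df.columns[std == 0])
        std = std.where(std > 0, 1.0)
        return cls(mean=mean, std=std, constant_features=constant)

    def apply(self, table):
        df = table.df
        if list(df.columns) != list(self.mean.index):
            missing = set(self.mean.index) - set(df.columns)
            extra = set(df.columns) - set(self.mean.index)
            if missing or extra:
                raise ValueError(
                    f"feature mismatch: missing {sorted(missing)[:5]}, "
                    f"extra {sorted(extra)[:5]}"
                )
            df = df[list(self.mean.index)]
        out = (df - self.mean) / self.std
        return table.with_values(out, state="zscored")

    def to_json(self) -> str:
        return json.dumps({
            "mean": self.mean.to_dict(),
            "std": self.std.to_dict(),
            "features": list(self.mean.index),
            "constant_features": list(self.constant_features),
        })

    @classmethod
    def from_json(cls, text: str) -> "ZScaler":
        obj = json.loads(text)
        feats = obj["features"]
        return cls(
            mean=pd.Series(obj["mean"]).reindex(feats),
            std=pd.Series(obj["std"]).reindex(feats),
            constant_features=obj["constant_features"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ZScaler":
        return cls.from_json(Path(path).read_text())


def zscore_fit_apply(train_table, test_table=None):
    """Fit a :class:`ZScaler` on the training table and apply it.

    Returns ``(train_scaled, scaler)`` or ``(train_scaled, test_scaled,
    scaler)`` when a test table is given.
    """
    scaler = ZScaler.fit(train_table)
    train_out = scaler.apply(train_table)
    if test_table is None:
        return train_out, scaler
    return train_out, scaler.apply(test_table), scaler


def _group_features(table: AbundanceTable, level: str) -> dict[str, list[str]]:
    if table.lineages is None:
        raise ValueError("aggregation requires taxonomy lineages")
    groups: dict[str, list[str]] = {}
    unassigned = []
    for feat in table.df.columns:
        label = table.lineages[feat].label_at(level)
        if label is None:
            unassigned.append(feat)
            label = f"unassigned-at-{level}"
        groups.setdefault(label, []).append(feat)
    if unassigned:
        warnings.warn(
            f"{len(unassigned)} features lack a name at {level!r}; "
            f"grouped as 'unassigned-at-{level}'"
        )
    return groups


def _sub_pca_components(block: np.ndarray, rng_sign: bool = True) -> np.ndarray:
    """Leading PCA scores of one taxon group.

    Keeps the smallest leading-component prefix whose cumulative explained
    variance ratio exceeds one half (always at least one component).  Each
    component's sign is fixed so its largest-magnitude loading is positive,
    making the merge deterministic across linear-algebra backends.
    """
    n, p = block.shape
    k = min(n, p)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(block)
    ratios = pca.explained_variance_ratio_
    if not np.isfinite(ratios).all() or ratios.sum() == 0:
        # constant group: a single zero-variance component
        return scores[:, :1] * 0.0
    n_keep = int(np.searchsorted(np.cumsum(ratios), 0.5, side="right")) + 1
    n_keep = min(max(n_keep, 1), k)
    comps = pca.components_[:n_keep]
    signs = np.sign(comps[np.arange(n_keep), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    return scores[:, :n_keep] * signs


def aggregate(table: AbundanceTable, config: PreprocessConfig) -> AbundanceTable:
    """Merge features to a taxonomy level by mean or group-wise sub-PCA.

    ``mean``: one output column per taxon = arithmetic mean of member
    columns.  ``sub-pca``: per-group PCA scores of the leading components
    covering more than half of the group variance; output ids are
    ``"<taxon>|pc<i>"``.  Lineages are dropped from sub-PCA output (the
    columns are no longer abundances of a single taxon).
    """
    groups = _group_features(table, config.taxonomy_level)
    pieces = {}
    if config.merge_method == "mean":
        for label, feats in groups.items():
            pieces[label] = table.df[feats].mean(axis=1)
        out = pd.DataFrame(pieces, index=table.df.index)
        lineages = None
        if table.lineages is not None:
            lineages = {}
            for label, feats in groups.items():
                if label.startswith("unassigned-at-"):
                    lineages = None
                    break
                lineages[label] = _truncate_lineage(
                    table.lineages[feats[0]], config.taxonomy_level
                )
        return AbundanceTable(out, lineages=lineages, state="merged")
    # sub-pca
    for label, feats in groups.items():
        scores = _sub_pca_components(table.df[feats].to_numpy(dtype=float))
        for j in range(scores.shape[1]):
            pieces[f"{label}|pc{j}"] = pd.Series(scores[:, j], index=table.df.index)
    out = pd.DataFrame(pieces, index=table.df.index)
    return AbundanceTable(out, lineages=None, state="merged")


def _truncate_lineage(lineage, level):
    from .taxonomy import TaxonomyLineage
    upto = RANKS.index(level) + 1
    return TaxonomyLineage(lineage.levels[:upto], prefixed=lineage.prefixed)


def preprocess_microbiome(table: AbundanceTable,
                          config: PreprocessConfig | None = None,
                          scaler: ZScaler | None = None):
    """Full microbiome chain ending in z-scored features.

    ``sub-pca`` merging operates on log10-transformed abundances
    (log -> sub-PCA -> z-score); ``mean`` merging averages raw abundances
    first (mean -> log -> z-score).  Aggregation runs only when lineages
    are available; tables without lineages go straight to log (if still on
    an abundance scale) and z-score.  When ``scaler`` is given it is
    applied instead of fitting a new one (test-time use).  Returns
    ``(table, scaler)``.
    """
    config = config or PreprocessConfig()
    if table.lineages is not None and config.merge_method == "sub-pca":
        logged = aggregate(normalize_log(table, config.log_epsilon), config)
    elif table.lineages is not None:
        logged = normalize_log(aggregate(table, config), config.log_epsilon)
    else:
        logged = normalize_log(table, config.log_epsilon)
    if not config.zscore:
        return logged, None
    if scaler is None:
        return zscore_fit_apply(logged)
    return scaler.apply(logged), scaler


def preprocess_metabolites(table: MetaboliteTable,
                           config: PreprocessConfig | None = None,
                           scaler: ZScaler | None = None):
    """Full metabolome chain: sample-relative -> log -> [z-score]."""
    config = config or PreprocessConfig()
    rel = normalize_relative(table, axis="sample-wise")
    logged = normalize_log(rel, config.log_epsilon)
    if not config.zscore:
        return logged, None
    if scaler is None:
        return zscore_fit_apply(logged)
    return scaler.apply(logged), scaler
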