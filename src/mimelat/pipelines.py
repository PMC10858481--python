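"""End-to-end estimators: preprocessing chain + predictor, one object.

Each pipeline owns its scalers, fit on training data only.  They share a
small protocol used by the transfer and sampling-curve analyses:

``fit(mi_table, me_table)``
    preprocess the raw/relative tables and train the predictor;
``predict(mi_table, normalize)``
    predicted metabolites for new microbiome samples;
``score(mi_table, me_table, normalize)``
    per-metabolite Spearman correlations against the given truth.

``normalize='train'`` applies the training scalers to the new samples
(the within-dataset protocol); ``normalize='self'`` standardizes the new
dataset with its own statistics (the cross-dataset protocol, where each
cohort is normalized separately and no training statistic touches the
test cohort).  Spearman scoring is invariant to the per-metabolite affine
part of that choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baselines import DEFAULT_L1, fit_log_network, fit_nmf_relation
from .evaluation import (MetabolitePredictionReport, SplitPlan, make_splits,
                         predict_condition, score_metabolites)
from .model import LatentConfig, LatentMetaboliteModel
from .preprocess import (DEFAULT_LOG_EPSILON, normalize_log,
                         normalize_relative, zscore_fit_apply)
from .tables import AbundanceTable, MetaboliteTable, PairedDataset


def _mi_chain(table: AbundanceTable, epsilon: float):
    """log10(x+eps) on abundance-scale tables; pass z-scored/log through."""
    if table.state in {"log", "zscored"}:
        return table
    return normalize_log(table, epsilon)


def _me_chain(table: MetaboliteTable, epsilon: float):
    if table.state in {"log", "zscored"}:
        return table
    if table.state != "relative":
        table = normalize_relative(table, axis="sample-wise")
    return normalize_log(table, epsilon)


class LatentPipeline:
    """Preprocessing + latent encoder/decoder model."""

    tag = "latent"

    def __init__(self, config: LatentConfig | None = None,
                 log_epsilon: float = DEFAULT_LOG_EPSILON, **kwargs):
        self.config = config or LatentConfig(**kwargs)
        self.log_epsilon = log_epsilon

    def fit(self, mi_table: AbundanceTable, me_table: MetaboliteTable):
        mi_log = _mi_chain(mi_table, self.log_epsilon)
        me_log = _me_chain(me_table, self.log_epsilon)
        mi_z, self.mi_scaler_ = zscore_fit_apply(mi_log)
        me_z, self.me_scaler_ = zscore_fit_apply(me_log)
        self.model_ = LatentMetaboliteModel(self.config).fit(mi_z.df, me_z.df)
        return self

    def _prep_mi(self, mi_table: AbundanceTable, normalize: str) -> pd.DataFrame:
        mi_log = _mi_chain(mi_table, self.log_epsilon)
        if normalize == "self":
            mi_z, _ = zscore_fit_apply(mi_log)
        else:
            mi_z = self.mi_scaler_.apply(mi_log)
        return mi_z.df

    def predict(self, mi_table: AbundanceTable, normalize: str = "train"):
        return self.model_.predict(self._prep_mi(mi_table, normalize))

    def embed(self, mi_table: AbundanceTable, normalize: str = "train"):
        return self.model_.embed(self._prep_mi(mi_table, normalize))

    def truth(self, me_table: MetaboliteTable, normalize: str = "train"):
        me_log = _me_chain(me_table, self.log_epsilon)
        if normalize == "self":
            me_z, _ = zscore_fit_apply(me_log)
        else:
            me_z = self.me_scaler_.apply(me_log)
        return me_z.df

    def score(self, mi_table, me_table, normalize: str = "train",
              ) -> MetabolitePredictionReport:
        pred = self.predict(mi_table, normalize)
        true = self.truth(me_table, normalize)
        return score_metabolites(true, pred, model_tag=self.tag)


class LogNetPipeline(LatentPipeline):
    """Preprocessing + low-rank log-linear network."""

    tag = "lognet"

    def __init__(self, rank: int = 6,
                 log_epsilon: float = DEFAULT_LOG_EPSILON):
        self.rank = rank
        self.log_epsilon = log_epsilon

    def fit(self, mi_table, me_table):
        mi_log = _mi_chain(mi_table, self.log_epsilon)
        me_log = _me_chain(me_table, self.log_epsilon)
        mi_z, self.mi_scaler_ = zscore_fit_apply(mi_log)
        me_z, self.me_scaler_ = zscore_fit_apply(me_log)
        self.model_ = fit_log_network(mi_z.df, me_z.df, rank=self.rank)
        return self

    def predict(self, mi_table, normalize: str = "train"):
        return self.model_.predict(self._prep_mi(mi_table, normalize))

    def embed(self, *a, **k):  # pragma: no cover - no latent layer
        raise NotImplementedError("the log-linear network has no latent layer")


class NmfPipeline:
    """Non-negative linear relation on relative-scale data.

    The microbiome is normalized taxon-wise (each taxon divided by its sum
    across the samples at hand), which equalizes column norms so that rare
    producer taxa are discoverable under the L1 penalty; metabolites are
    normalized per sample.
    """

    tag = "nmf"

    def __init__(self, l1_strength: float = DEFAULT_L1, seed: int = 0):
        self.l1_strength = l1_strength
        self.seed = seed

    @staticmethod
    def _mi_rel(table):
        return normalize_relative(
            table.with_values(table.df, state="raw"), axis="taxon-wise").df

    @staticmethod
    def _me_rel(table):
        if table.state == "relative":
            return table.df
        return normalize_relative(table, axis="sample-wise").df

    def fit(self, mi_table, me_table):
        self.relation_ = fit_nmf_relation(self._mi_rel(mi_table),
                                          self._me_rel(me_table),
                                          l1_strength=self.l1_strength,
                                          seed=self.seed)
        self.metabolite_ids_ = list(self._me_rel(me_table).columns)
        return self

    def predict(self, mi_table, normalize: str = "train"):
        Mi = self._mi_rel(mi_table)
        return pd.DataFrame(self.relation_.predict(Mi), index=Mi.index,
                            columns=self.metabolite_ids_)

    def truth(self, me_table, normalize: str = "train"):
        return self._me_rel(me_table)

    def score(self, mi_table, me_table, normalize: str = "train",
              ) -> MetabolitePredictionReport:
        pred = self.predict(mi_table)
        true = self.truth(me_table)
        return score_metabolites(true, pred, model_tag=self.tag)


def _subset(ds: PairedDataset, idx) -> tuple[AbundanceTable, MetaboliteTable]:
    mi = ds.microbiome
    me = ds.metabolites
    mi_s = mi.with_values(mi.df.iloc[idx], state=mi.state)
    me_s = me.with_values(me.df.iloc[idx], state=me.state)
    return mi_s, me_s


def within_dataset_scc(ds: PairedDataset, factory, splits: SplitPlan | None = None,
                       n_repeats: int = 10, test_fraction: float = 0.2,
                       seed: int = 0) -> MetabolitePredictionReport:
    """80/20 x n_repeats within-dataset metabolite prediction."""
    splits = splits or make_splits(ds.n_samples, test_fraction, n_repeats, seed)
    rows = []
    tag = ""
    for train, test in splits.splits:
        est = factory()
        est.fit(*_subset(ds, train))
        rep = est.score(*_subset(ds, test), normalize="train")
        rows.append(rep.scc)
        tag = rep.model_tag
    return MetabolitePredictionReport(scc=np.vstack(rows), model_tag=tag)


def hybrid_sampling_curve(paired: PairedDataset,
                          microbiome_only: AbundanceTable | None,
                          labels, n_pairs_grid, config: LatentConfig,
                          n_draws: int = 10, test_fraction: float = 0.2,
                          seed: int = 0, task: str = "binary") -> pd.DataFrame:
    """Condition-prediction gain of the latent code vs microbiome alone as
    a function of how many paired (microbiome + metabolome) samples train
    the representation.

    For each grid value ``n``: draw ``n`` pairs at random, train the
    latent model on them, embed the whole cohort (paired plus
    microbiome-only samples), then predict the condition once from the
    embedding ``Z`` and once from the processed microbiome on a common
    80/20 split; repeat ``n_draws`` times.  Reports the per-``n`` mean and
    standard error of the AUC (or Spearman) difference ``Z - Mi``.
    """
    mi_all = paired.microbiome
    if microbiome_only is not None:
        joint = pd.concat([mi_all.df, microbiome_only.df], axis=0)
        mi_all = AbundanceTable(joint, lineages=None, state=mi_all.state)
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != mi_all.df.shape[0]:
        raise ValueError("labels must cover paired + microbiome-only samples")

    mi_log = _mi_chain(mi_all, DEFAULT_LOG_EPSILON)
    mi_feats, _ = zscore_fit_apply(mi_log)
    n_paired = paired.n_samples
    rng = np.random.default_rng(seed)
    rows = []
    for n_pairs in n_pairs_grid:
        if n_pairs > n_paired:
            import warnings
            warnings.warn(f"grid value {n_pairs} exceeds paired samples, skipped")
            continue
        deltas = []
        for draw in range(n_draws):
            pick = rng.choice(n_paired, size=n_pairs, replace=False)
            est = LatentPipeline(config)
            est.fit(*_subset(paired, np.sort(pick)))
            Z = est.embed(mi_all).to_frame()
            splits = make_splits(Z.shape[0], test_fraction, n_repeats=1,
                                 seed=seed * 1000 + len(deltas) + n_pairs)
            rep_z = predict_condition(Z, labels, task, splits, "Z")
            rep_mi = predict_condition(mi_feats.df, labels, task, splits, "Mi")
            if rep_z.per_repeat.size and rep_mi.per_repeat.size:
                deltas.append(rep_z.per_repeat[0] - rep_mi.per_repeat[0])
        deltas = np.asarray(deltas)
        rows.append({
            "n_pairs": int(n_pairs),
            "delta_mean": float(deltas.mean()),
            "delta_sem": float(deltas.std(ddof=1) / np.sqrt(deltas.size))
            if deltas.size > 1 else 0.0,
            "n_draws": int(deltas.size),
        })
    return pd.DataFrame(rows)
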