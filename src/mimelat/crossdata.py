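"""Cross-cohort harmonization, core microbiome, transfer, and consistency.

Cohorts name metabolites differently, so metabolites are matched across
datasets by chemical formula (a user-supplied name -> formula table; no
live database queries).  Formulas are canonicalized by element counts and
rendered in Hill order, so ``CH3COOH`` and ``C2H4O2`` match; isomers
merge.  Taxa are matched at a chosen taxonomy level (order by default, to
maximize the cross-cohort intersection).

The core microbiome scores each taxon by the sum over cohorts of the
fraction of the cohort's samples in which it is present — a taxon present
in every sample of every one of ``k`` cohorts scores ``k``.

Transfer ("in"/"ex" learning) contrasts within-dataset 80/20 accuracy on
the restricted shared features against train-on-one / test-on-the-other
accuracy, with each dataset normalized separately.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import MetabolitePredictionReport
from .pipelines import within_dataset_scc
from .tables import AbundanceTable, MetaboliteTable, PairedDataset

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Element counts of a condensed chemical formula.

    Supports multi-letter elements, repeated blocks (``CH3COOH``) and
    parenthesized groups with multipliers (``Ca(OH)2``).
    """
    formula = formula.strip()
    if not formula:
        raise ValueError("empty formula")

    def walk(s: str, i: int) -> tuple[dict[str, int], int]:
        counts: dict[str, int] = {}
        while i < len(s):
            ch = s[i]
            if ch == ")":
                return counts, i
            if ch == "(":
                inner, j = walk(s, i + 1)
                if j >= len(s) or s[j] != ")":
                    raise ValueError(f"unbalanced parentheses in {formula!r}")
                j += 1
                mult = 0
                while j < len(s) and s[j].isdigit():
                    mult = mult * 10 + int(s[j])
                    j += 1
                mult = mult or 1
                for el, c in inner.items():
                    counts[el] = counts.get(el, 0) + c * mult
                i = j
                continue
            m = re.match(r"([A-Z][a-z]?)(\d*)", s[i:])
            if not m:
                raise ValueError(f"cannot parse formula {formula!r} at {s[i:]!r}")
            el = m.group(1)
            cnt = int(m.group(2)) if m.group(2) else 1
            counts[el] = counts.get(el, 0) + cnt
            i += len(m.group(0))
        return counts, i

    counts, i = walk(formula, 0)
    if i != len(formula):
        raise ValueError(f"unbalanced parentheses in {formula!r}")
    return counts


def canonical_formula(formula: str) -> str:
    """Hill-order rendering: C, then H, then other elements alphabetically
    (all alphabetical when carbon is absent)."""
    counts = parse_formula(formula)
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else []) + sorted(
            e for e in counts if e not in {"C", "H"})
    else:
        order = sorted(counts)
    return "".join(f"{e}{counts[e] if counts[e] > 1 else ''}" for e in order)


def _formula_lookup(formula_map) -> dict[str, str]:
    """name -> canonical formula from a two-column table or mapping."""
    if isinstance(formula_map, pd.DataFrame):
        if formula_map.shape[1] < 2:
            raise ValueError("formula map needs (name, formula) columns")
        items = zip(formula_map.iloc[:, 0], formula_map.iloc[:, 1])
    else:
        items = formula_map.items()
    out: dict[str, str] = {}
    for name, formula in items:
        canon = canonical_formula(str(formula))
        if name in out and out[name] != canon:
            raise ValueError(
                f"name {name!r} maps to two formulas: {out[name]} vs {canon}")
        out[str(name)] = canon
    return out


def harmonize_metabolites(names_a, names_b, formula_map):
    """Match metabolite names across two cohorts by canonical formula.

    Returns ``(matches, unmatched_a, unmatched_b)`` where ``matches`` is a
    DataFrame with columns ``name_a``, ``name_b``, ``formula``; names
    missing from the map (or whose formula has no partner) are listed as
    unmatched, never silently dropped.  Isomers (several names, one
    formula) are grouped under the shared formula.
    """
    lookup = _formula_lookup(formula_map)
    by_formula_a: dict[str, list] = {}
    by_formula_b: dict[str, list] = {}
    unmatched_a, unmatched_b = [], []
    for name in names_a:
        f = lookup.get(str(name))
        (by_formula_a.setdefault(f, []).append(name) if f
         else unmatched_a.append(name))
    for name in names_b:
        f = lookup.get(str(name))
        (by_formula_b.setdefault(f, []).append(name) if f
         else unmatched_b.append(name))
    rows = []
    for f in sorted(set(by_formula_a) & set(by_formula_b)):
        for na in by_formula_a[f]:
            for nb in by_formula_b[f]:
                rows.append({"name_a": na, "name_b": nb, "formula": f})
    for f in set(by_formula_a) - set(by_formula_b):
        unmatched_a.extend(by_formula_a[f])
    for f in set(by_formula_b) - set(by_formula_a):
        unmatched_b.extend(by_formula_b[f])
    matches = pd.DataFrame(rows, columns=["name_a", "name_b", "formula"])
    return matches, unmatched_a, unmatched_b


def _merge_by_formula(me: MetaboliteTable, lookup: dict[str, str],
                      keep: set[str]) -> pd.DataFrame:
    """Sum metabolite columns per canonical formula (isomers merge)."""
    groups: dict[str, list] = {}
    for name in me.df.columns:
        f = lookup.get(str(name))
        if f in keep:
            groups.setdefault(f, []).append(name)
    out = {f: me.df[cols].sum(axis=1) for f, cols in sorted(groups.items())}
    return pd.DataFrame(out, index=me.df.index)


def _taxa_labels(mi: AbundanceTable, level: str | None) -> dict[str, str]:
    if level is None or mi.lineages is None:
        return {f: f for f in mi.df.columns}
    out = {}
    for f in mi.df.columns:
        lab = mi.lineages[f].label_at(level)
        if lab is not None:
            out[f] = lab
    return out


@dataclass
class HarmonizedPair:
    """Two cohorts restricted to shared taxa and formula-matched metabolites."""

    dataset_a: PairedDataset
    dataset_b: PairedDataset
    shared_taxa: list
    shared_formulas: list
    dropped: dict = field(default_factory=dict)


def harmonize_pair(ds_a: PairedDataset, ds_b: PairedDataset, formula_map,
                   level: str | None = "order") -> HarmonizedPair:
    """Restrict two cohorts to their shared feature space.

    Taxa are matched by name at ``level`` (raw feature ids when lineages
    are absent or ``level`` is None); metabolites by canonical formula,
    summing isomers.  Output feature ids are identical and identically
    ordered across the two datasets.
    """
    lab_a = _taxa_labels(ds_a.microbiome, level)
    lab_b = _taxa_labels(ds_b.microbiome, level)
    shared_taxa = sorted(set(lab_a.values()) & set(lab_b.values()))
    if not shared_taxa:
        warnings.warn("no shared taxa between the two datasets")

    lookup = _formula_lookup(formula_map)
    matches, un_a, un_b = harmonize_metabolites(
        ds_a.metabolites.df.columns, ds_b.metabolites.df.columns, formula_map)
    shared_formulas = sorted(matches["formula"].unique())
    if len(shared_formulas) < 2:
        raise ValueError("fewer than 2 shared metabolites after harmonization")

    def restrict(ds: PairedDataset, labels: dict) -> PairedDataset:
        inv: dict[str, list] = {}
        for feat, lab in labels.items():
            if lab in shared_taxa:
                inv.setdefault(lab, []).append(feat)
        mi_df = pd.DataFrame(
            {lab: ds.microbiome.df[inv[lab]].sum(axis=1) for lab in shared_taxa},
            index=ds.microbiome.df.index)
        mi = AbundanceTable(mi_df, lineages=None, state=ds.microbiome.state)
        me_df = _merge_by_formula(ds.metabolites, lookup, set(shared_formulas))
        me = MetaboliteTable(me_df, formulas={f: f for f in me_df.columns},
                             state="raw")
        return PairedDataset(mi, me, ds.metadata, name=ds.name)

    dropped = {
        "taxa_a": sorted(set(lab_a.values()) - set(shared_taxa)),
        "taxa_b": sorted(set(lab_b.values()) - set(shared_taxa)),
        "metabolites_a": sorted(map(str, un_a)),
        "metabolites_b": sorted(map(str, un_b)),
    }
    return HarmonizedPair(restrict(ds_a, lab_a), restrict(ds_b, lab_b),
                          shared_taxa, shared_formulas, dropped)


@dataclass
class CoreMicrobiome:
    """Taxa scored by summed per-cohort presence fractions."""

    presence: pd.DataFrame      # taxa x cohorts, presence fractions
    aggregate: pd.Series        # sum across cohorts, descending
    core_taxa: list             # aggregate >= threshold
    threshold: float


def core_microbiome(datasets, min_aggregate_score: float,
                    level: str | None = "order",
                    min_abundance: float = 0.0) -> CoreMicrobiome:
    """Presence-based core microbiome across cohorts.

    Presence of a taxon in a sample means relative abundance strictly
    above ``min_abundance`` (default 0).  The aggregate score of a taxon
    is the sum over cohorts of its per-cohort presence fraction, so it
    ranges from 0 to the number of cohorts.
    """
    cols = {}
    for ds in datasets:
        mi = ds.microbiome if isinstance(ds, PairedDataset) else ds
        labels = _taxa_labels(mi, level)
        inv: dict[str, list] = {}
        for feat, lab in labels.items():
            inv.setdefault(lab, []).append(feat)
        frac = {lab: float((mi.df[feats].sum(axis=1) > min_abundance).mean())
                for lab, feats in inv.items()}
        name = ds.name if isinstance(ds, PairedDataset) else "cohort"
        key = name if name not in cols else f"{name}_{len(cols)}"
        cols[key] = pd.Series(frac)
    presence = pd.DataFrame(cols).fillna(0.0)
    aggregate = presence.sum(axis=1).sort_values(ascending=False)
    presence = presence.loc[aggregate.index]
    core = list(aggregate[aggregate >= min_aggregate_score].index)
    if not core:
        warnings.warn("empty core microbiome at this threshold")
    return CoreMicrobiome(presence=presence, aggregate=aggregate,
                          core_taxa=core, threshold=min_aggregate_score)


def in_ex_learning(pair: HarmonizedPair, model_factory,
                   n_repeats: int = 10, test_fraction: float = 0.2,
                   seed: int = 0) -> dict[str, MetabolitePredictionReport]:
    """Within-dataset vs cross-dataset metabolite prediction.

    "in": 80/20 x ``n_repeats`` within each dataset on the restricted
    features (the same split protocol as full-feature runs).  "ex": train
    on the whole of one dataset, test on the whole of the other, in both
    directions; each dataset is normalized separately and no training
    statistic is derived from the test cohort.
    """
    ds_a, ds_b = pair.dataset_a, pair.dataset_b
    out = {}
    out["in_a"] = within_dataset_scc(ds_a, model_factory, n_repeats=n_repeats,
                                     test_fraction=test_fraction, seed=seed)
    out["in_b"] = within_dataset_scc(ds_b, model_factory, n_repeats=n_repeats,
                                     test_fraction=test_fraction, seed=seed + 1)
    for src, dst, key in ((ds_a, ds_b, "ex_a_to_b"), (ds_b, ds_a, "ex_b_to_a")):
        before = dst.microbiome.df.to_numpy().copy()
        est = model_factory()
        est.fit(src.microbiome, src.metabolites)
        rep = est.score(dst.microbiome, dst.metabolites, normalize="self")
        # transfer must never mutate the test cohort
        assert np.array_equal(before, dst.microbiome.df.to_numpy())
        out[key] = rep
    return out


@dataclass
class ConsistencyMatrix:
    """Microbe-metabolite correlation entries per dataset.

    ``matrix`` holds SCCs where significant (p below the threshold), NaN
    elsewhere; ``all_scc`` the unthresholded values; ``pair_means`` the
    per-pair mean SCC over all datasets containing the pair (significant
    or not), restricted to pairs present in at least two datasets.
    """

    matrix: pd.DataFrame
    all_scc: pd.DataFrame
    pair_means: pd.Series
    p_threshold: float


def pair_consistency(datasets, p_threshold: float = 0.05,
                     metabolite_subset=None,
                     level: str | None = "order") -> ConsistencyMatrix:
    """Cross-dataset consistency of microbe-metabolite correlations.

    Pairs are keyed by (taxon label at ``level``, canonical metabolite
    formula).  Per dataset, the Spearman correlation and p-value of every
    present pair is computed on the relative/raw values; the thresholded
    matrix keeps entries with ``p < p_threshold``.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    per_ds = {}
    for ds in datasets:
        labels = _taxa_labels(ds.microbiome, level)
        inv: dict[str, list] = {}
        for feat, lab in labels.items():
            inv.setdefault(lab, []).append(feat)
        forms = ds.metabolites.formulas or {m: m for m in ds.metabolites.df.columns}
        fcols: dict[str, list] = {}
        for met, f in forms.items():
            canon = canonical_formula(f)
            if metabolite_subset is not None and canon not in metabolite_subset:
                continue
            fcols.setdefault(canon, []).append(met)
        scc = {}
        for lab, feats in inv.items():
            x = ds.microbiome.df[feats].sum(axis=1).to_numpy()
            if np.ptp(x) == 0:
                continue
            for f, mets in fcols.items():
                y = ds.metabolites.df[mets].sum(axis=1).to_numpy()
                if np.ptp(y) == 0:
                    continue
                r = stats.spearmanr(x, y)
                scc[(lab, f)] = (float(r.statistic), float(r.pvalue))
        per_ds[ds.name] = scc
    pairs = sorted(set().union(*[set(s) for s in per_ds.values()]))
    idx = pd.MultiIndex.from_tuples(pairs, names=["taxon", "formula"])
    all_scc = pd.DataFrame(index=idx, columns=list(per_ds), dtype=float)
    sig = pd.DataFrame(index=idx, columns=list(per_ds), dtype=float)
    for name, scc in per_ds.items():
        for key, (r, p) in scc.items():
            all_scc.loc[key, name] = r
            if p < p_threshold:
                sig.loc[key, name] = r
    counts = all_scc.notna().sum(axis=1)
    pair_means = all_scc[counts >= 2].mean(axis=1, skipna=True)
    return ConsistencyMatrix(matrix=sig, all_scc=all_scc,
                             pair_means=pair_means, p_threshold=p_threshold)
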