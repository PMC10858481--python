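"""Typed sample x feature tables for paired microbiome-metabolome cohorts.

The two central containers wrap a :class:`pandas.DataFrame` (rows = samples,
columns = features) together with light provenance: taxonomy lineages for
microbial features, chemical formulas for metabolites, and a ``state`` tag
recording which preprocessing steps the values have been through
(``raw`` -> ``relative``/``merged`` -> ``log`` -> ``zscored``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyLineage, parse_taxonomy

STATES = ("raw", "relative", "log", "zscored", "merged")


def _check_frame(df: pd.DataFrame, state: str, require_nonneg: bool) -> None:
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}, expected one of {STATES}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TypeError("table values must be numeric")
    if require_nonneg and state == "raw" and np.nanmin(values, initial=0) < 0:
        raise ValueError("state='raw' requires non-negative values")


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with optional taxonomy lineages."""

    df: pd.DataFrame
    lineages: Mapping[str, TaxonomyLineage] | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        _check_frame(self.df, self.state, require_nonneg=True)
        if self.lineages is not None:
            missing = [f for f in self.df.columns if f not in self.lineages]
            if missing:
                raise ValueError(f"features without lineage: {missing[:5]}...")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def with_values(self, df: pd.DataFrame, state: str,
                    keep_lineages: bool = True) -> "AbundanceTable":
        lin = self.lineages if keep_lineages else None
        if lin is not None:
            lin = {f: lin[f] for f in df.columns if f in lin}
            if len(lin) != df.shape[1]:
                lin = None
        return AbundanceTable(df, lineages=lin, state=state)


@dataclass
class MetaboliteTable:
    """Samples x metabolites concentration matrix with optional formulas."""

    df: pd.DataFrame
    formulas: Mapping[str, str] | None = None
    state: str = "raw"
    zero_rows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_frame(self.df, self.state, require_nonneg=True)
        if self.state == "relative":
            sums = self.df.sum(axis=1).to_numpy()
            bad = ~np.isclose(sums, 1.0, atol=1e-9)
            zero = np.isclose(sums, 0.0)
            # all-zero input rows are flagged, not silently kept as "relative"
            if np.any(bad & ~zero):
                raise ValueError("state='relative' requires unit row sums")
            self.zero_rows = list(self.df.index[zero])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def with_values(self, df: pd.DataFrame, state: str) -> "MetaboliteTable":
        forms = self.formulas
        if forms is not None:
            forms = {m: forms[m] for m in df.columns if m in forms}
        return MetaboliteTable(df, formulas=forms, state=state)


@dataclass
class PairedDataset:
    """Aligned microbiome, metabolome, and metadata for N shared samples."""

    microbiome: AbundanceTable
    metabolites: MetaboliteTable
    metadata: pd.DataFrame | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        mi, me = self.microbiome.df, self.metabolites.df
        if list(mi.index) != list(me.index):
            shared = mi.index.intersection(me.index)
            if len(shared) == 0:
                raise ValueError("no shared samples between views")
            self.microbiome = replace(self.microbiome, df=mi.loc[shared])
            self.metabolites = replace(self.metabolites, df=me.loc[shared])
        if self.metadata is not None:
            self.metadata = self.metadata.loc[self.microbiome.df.index]

    @property
    def n_samples(self) -> int:
        return self.microbiome.df.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return self.microbiome.sample_ids


def _read_frame(path: str | Path, orientation: str) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if orientation == "auto":
        # lineage-like row labels mean the file stores features as rows
        semi = sum(";" in ix for ix in df.index[: min(len(df), 20)])
        orientation = "features-as-rows" if semi > 0 else "samples-as-rows"
    if orientation == "features-as-rows":
        df = df.T
    elif orientation != "samples-as-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def _check_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().to_numpy().any() and not df.isna().to_numpy().any():
        r, c = np.argwhere(out.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {df.index[r]!r}, feature {df.columns[c]!r}"
        )
    return out


def read_table(path: str | Path, kind: str = "abundance",
               orientation: str = "auto"):
    """Read a CSV/TSV table as a typed container.

    Parameters
    ----------
    path:
        CSV (comma) or TSV/TXT (tab) file; first column holds the row ids.
    kind:
        ``"abundance"``, ``"metabolite"`` or ``"metadata"``.
    orientation:
        ``"samples-as-rows"``, ``"features-as-rows"``, or ``"auto"``
        (features-as-rows is assumed when row labels look like lineages).
    """
    df = _read_frame(path, orientation)
    if kind == "metadata":
        return df
    df = _check_numeric(df)
    if kind == "abundance":
        lineages = None
        if all(";" in c for c in df.columns):
            lineages = {c: parse_taxonomy(c) for c in df.columns}
        return AbundanceTable(df, lineages=lineages, state="raw")
    if kind == "metabolite":
        return MetaboliteTable(df, state="raw")
    raise ValueError(f"unknown kind {kind!r}")


def write_table(table, path: str | Path) -> None:
    """Write any table container (or DataFrame) to CSV/TSV by extension."""
    df = table if isinstance(table, pd.DataFrame) else table.df
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    df.to_csv(path, sep=sep)


def align_tables(mi: AbundanceTable, me: MetaboliteTable,
                 metadata: pd.DataFrame | None = None,
                 name: str = "dataset") -> PairedDataset:
    """Intersect sample ids across views and return a PairedDataset."""
    shared = mi.df.index.intersection(me.df.index)
    if len(shared) < len(mi.df.index) or len(shared) < len(me.df.index):
        warnings.warn(
            f"{name}: keeping {len(shared)} shared samples "
            f"(microbiome {len(mi.df.index)}, metabolome {len(me.df.index)})"
        )
    mi = replace(mi, df=mi.df.loc[shared])
    me = replace(me, df=me.df.loc[shared])
    if metadata is not None:
        metadata = metadata.loc[shared]
    return PairedDataset(mi, me, metadata, name=name)
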