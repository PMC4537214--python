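"""Reading, validation, filtering and alignment of input tables.

Input formats are plain TSV: features as rows with a header of sample ids
(the usual omics export orientation; a transposed reader flag exists),
phenotypes as samples x columns with explicit missing markers (empty cell
or "NA"), and splits as samples x binary columns.  Each feature is typed
as mutation (binary), expression or copy_number (continuous) through a
companion metadata table; the type drives the standard pre-modeling
filters (mutation prevalence < 10%, expression variance < 0.2, copy-number
variance < 0.15, IC50 phenotypes with > 80% invalid entries dropped and
the rest log-transformed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .l0 import Dataset

__all__ = [
    "FeatureTable",
    "PhenotypeTable",
    "SplitSet",
    "load_feature_table",
    "load_phenotype_table",
    "load_split_set",
    "filter_mutations",
    "filter_variance",
    "prepare_phenotypes",
    "align",
]

FEATURE_DTYPES = ("mutation", "expression", "copy_number")
PHENO_METRICS = ("ACT", "IC50")
NA_VALUES = ["", "NA", "NaN", "nan"]


@dataclass
class FeatureTable:
    """Genomic features: ``values`` is features x samples, with per-feature
    gene and dtype metadata."""

    values: pd.DataFrame           # index = feature names, columns = sample ids
    meta: pd.DataFrame             # index = feature names, columns = [gene, dtype]

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0:
            raise ValueError("no features")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = self.values.index.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"features without metadata: {list(missing)[:5]}")
        self.meta = self.meta.loc[self.values.index]
        bad = ~self.meta["dtype"].isin(FEATURE_DTYPES)
        if bad.any():
            raise ValueError(
                f"unknown feature dtype(s): {sorted(self.meta.loc[bad, 'dtype'].unique())}"
            )
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("feature table contains non-numeric cells")
        if np.isnan(vals).any():
            raise ValueError("feature table contains missing values")
        mut = self.values.loc[self.meta["dtype"] == "mutation"].to_numpy()
        if mut.size and not np.all((mut == 0) | (mut == 1)):
            raise ValueError("mutation features must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class PhenotypeTable:
    """Drug-sensitivity phenotypes: samples x phenotypes, NaN = missing."""

    values: pd.DataFrame           # index = sample ids, columns = phenotype names
    meta: pd.DataFrame             # index = phenotype names, columns = [drug, metric]

    def __post_init__(self) -> None:
        if self.values.shape[1] == 0:
            raise ValueError("no phenotypes")
        missing = self.values.columns.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"phenotypes without metadata: {list(missing)[:5]}")
        self.meta = self.meta.loc[self.values.columns]
        bad = ~self.meta["metric"].isin(PHENO_METRICS)
        if bad.any():
            raise ValueError(
                f"unknown phenotype metric(s): {sorted(self.meta.loc[bad, 'metric'].unique())}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class SplitSet:
    """Candidate binary splits: samples x splits, values in {0, 1}."""

    indicators: pd.DataFrame       # index = sample ids, columns = split names

    def __post_init__(self) -> None:
        vals = self.indicators.to_numpy(dtype=float)
        if vals.size and not np.all((vals == 0) | (vals == 1)):
            raise ValueError("split indicators must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicators.index)

    @property
    def T(self) -> int:
        return self.indicators.shape[1]


def load_feature_table(path, meta_path, transposed: bool = False) -> FeatureTable:
    """Read a feature TSV (rows = features unless ``transposed``) plus its
    [feature, gene, dtype] metadata TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("no features")
    if transposed:
        df = df.T
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric cell in feature table: {e}") from None
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    meta.columns = [c.lower() for c in meta.columns]
    df.index = df.index.astype(str)
    meta.index = meta.index.astype(str)
    return FeatureTable(values=df, meta=meta)


def load_phenotype_table(path, meta_path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES, keep_default_na=False)
    df = df.astype(float)
    df.index = df.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    meta.columns = [c.lower() for c in meta.columns]
    meta.index = meta.index.astype(str)
    return PhenotypeTable(values=df, meta=meta)


def load_split_set(path) -> SplitSet:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    df.index = df.index.astype(str)
    return SplitSet(indicators=df)


def filter_mutations(ft: FeatureTable, min_frac: float = 0.10) -> FeatureTable:
    """Drop mutation features mutated in fewer than ``min_frac`` of samples
    (strict <) or in none at all; other dtypes pass through untouched."""
    is_mut = ft.meta["dtype"] == "mutation"
    frac = ft.values.mean(axis=1)
    drop = is_mut & ((frac < min_frac) | (frac == 0))
    keep = ft.values.index[~drop]
    return FeatureTable(values=ft.values.loc[keep], meta=ft.meta.loc[keep])


def filter_variance(ft: FeatureTable, expr_min: float = 0.2, cnv_min: float = 0.15) -> FeatureTable:
    """Drop expression features with sample variance < ``expr_min`` and
    copy-number features with variance < ``cnv_min`` (unbiased, n-1)."""
    var = ft.values.var(axis=1, ddof=1)
    dt = ft.meta["dtype"]
    drop = ((dt == "expression") & (var < expr_min)) | ((dt == "copy_number") & (var < cnv_min))
    keep = ft.values.index[~drop]
    return FeatureTable(values=ft.values.loc[keep], meta=ft.meta.loc[keep])


def prepare_phenotypes(pt: PhenotypeTable, ic50_max_missing: float = 0.8) -> PhenotypeTable:
    """Drop IC50 phenotypes with too many invalid entries; log-transform
    (natural log) the survivors.  ACT phenotypes pass through bit-for-bit."""
    vals = pt.values.copy()
    keep = []
    for col in vals.columns:
        if pt.meta.loc[col, "metric"] == "IC50":
            miss = vals[col].isna().mean()
            if miss > ic50_max_missing:
                continue
            obs = vals[col].dropna()
            if (obs <= 0).any():
                cell = obs[obs <= 0].index[0]
                raise ValueError(
                    f"non-positive IC50 value for phenotype {col!r}, sample {cell!r}: "
                    "cannot log-transform"
                )
            vals[col] = np.log(vals[col])
        keep.append(col)
    if not keep:
        raise ValueError("no phenotypes survive IC50 filtering")
    return PhenotypeTable(values=vals[keep], meta=pt.meta.loc[keep])


def align(ft: FeatureTable, pt: PhenotypeTable, ss: SplitSet | None = None) -> Dataset:
    """Restrict all tables to the shared sample ids, in a common order.

    Samples are ordered lexicographically by id, so the result does not
    depend on the row/column order of any input.  Splits leaving fewer
    than two samples on either side are dropped with a warning.
    """
    common = set(ft.sample_ids) & set(pt.sample_ids)
    if ss is not None and ss.T > 0:
        common &= set(ss.sample_ids)
    ids = sorted(common)
    if not ids:
        raise ValueError("no samples shared between the input tables")

    X = ft.values[ids].to_numpy(dtype=float).T           # samples x features
    Y = pt.values.loc[ids].to_numpy(dtype=float)
    if ss is not None and ss.T > 0:
        Zdf = ss.indicators.loc[ids]
        ones = Zdf.sum(axis=0)
        ok = (ones >= 2) & (len(ids) - ones >= 2)
        if not ok.all():
            warnings.warn(
                f"dropping splits with <2 samples on a side: {list(Zdf.columns[~ok])}"
            )
        Zdf = Zdf.loc[:, ok]
        Z = Zdf.to_numpy(dtype=float)
        split_names = list(Zdf.columns)
    else:
        Z = np.zeros((len(ids), 0))
        split_names = []

    return Dataset(
        X=X,
        Y=Y,
        Z=Z,
        ids=ids,
        feature_names=list(ft.values.index),
        phenotype_names=list(pt.values.columns),
        split_names=split_names,
        binary_mask=(ft.meta["dtype"] == "mutation").to_numpy(),
    )
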