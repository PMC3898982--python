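"""Probe-to-gene collapsing and z-normalization of expression matrices.

Microarray platforms measure a gene with one or more probes.  Before a
signature can be scored across platforms, the matrix is collapsed to one row
per gene symbol -- for multi-probe genes the probe with the highest mean
expression is kept -- and every gene row is z-normalized across samples to
mean zero and unit standard deviation, so that a signature score is an
average of comparable quantities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """A features x samples matrix, optionally with a probe-to-gene map.

    ``gene_map`` absent means rows are already gene symbols.
    """

    values: pd.DataFrame
    gene_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise PreprocessError(f"duplicate sample_ids (e.g. {dup!r})")
        if self.values.isna().all(axis=1).any():
            bad = self.values.index[self.values.isna().all(axis=1)][0]
            raise PreprocessError(f"entirely-missing row {bad!r}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneMatrix:
    """One row per unique gene symbol; ``normalized`` marks z-scored rows."""

    values: pd.DataFrame
    normalized: bool = False
    dropped_constant: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise PreprocessError(f"duplicate gene symbol {dup!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def collapse_probes(m: ExpressionMatrix, max_missing_frac: float = 0.5) -> GeneMatrix:
    """Collapse a probe-level matrix to one row per gene.

    For genes measured by multiple probes the probe with the highest
    across-sample mean is retained (ties broken by input order).  Unmapped
    probes are dropped with a logged count, as are probes missing in more
    than ``max_missing_frac`` of samples.
    """
    vals = m.values
    if m.gene_map is not None:
        genes = pd.Series([m.gene_map.get(f) for f in vals.index], index=vals.index)
        unmapped = genes.isna()
        if unmapped.all():
            raise PreprocessError("no mappable features")
        if unmapped.any():
            log.info("collapse_probes: dropping %d unmapped features", int(unmapped.sum()))
            vals = vals.loc[~unmapped.values]
            genes = genes.loc[~unmapped.values]
    else:
        genes = pd.Series(vals.index, index=vals.index)

    missing_frac = vals.isna().mean(axis=1)
    too_missing = missing_frac > max_missing_frac
    if too_missing.any():
        log.warning("collapse_probes: dropping %d features missing in >%d%% of samples",
                    int(too_missing.sum()), int(100 * max_missing_frac))
        vals = vals.loc[~too_missing.values]
        genes = genes.loc[~too_missing.values]
        if vals.empty:
            raise PreprocessError("no mappable features")

    frame = pd.DataFrame({
        "gene": genes.values,
        "mean": vals.mean(axis=1, skipna=True).values,
        "pos": np.arange(len(vals)),
    })
    # stable sort: among equal means the earlier probe wins
    frame = frame.sort_values(["gene", "mean"], ascending=[True, False], kind="mergesort")
    chosen = frame.drop_duplicates("gene", keep="first").sort_values("pos")
    out = vals.iloc[chosen["pos"].values].copy()
    out.index = pd.Index(chosen["gene"].values, name="gene")
    return GeneMatrix(out, normalized=False)


def znormalize(m: GeneMatrix) -> GeneMatrix:
    """Z-normalize each gene row across samples (sample sd, n-1 divisor).

    Constant rows cannot be normalized; they are excluded with a warning and
    recorded in ``dropped_constant``.  Idempotent on already-normalized input.
    """
    if m.values.shape[1] < 2:
        raise PreprocessError("znormalize requires at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mu = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if constant.any():
        names = tuple(m.values.index[constant])
        log.warning("znormalize: excluding %d constant rows", len(names))
    else:
        names = ()
    z = (vals - mu) / np.where(sd == 0, np.nan, sd)
    out = pd.DataFrame(z[~constant], index=m.values.index[~constant],
                       columns=m.values.columns)
    return GeneMatrix(out, normalized=True,
                      dropped_constant=m.dropped_constant + names)


def log_transform(m: GeneMatrix) -> GeneMatrix:
    """log2(x+1) transform for count-scale data (off by default in pipelines;
    signature scores on RNA-seq are computed on normalized counts directly)."""
    if (m.values.to_numpy() < 0).any():
        raise PreprocessError("log_transform requires non-negative values")
    return replace(m, values=np.log2(m.values + 1.0), normalized=False)
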