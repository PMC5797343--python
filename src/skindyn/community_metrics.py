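"""Temporal stability signatures.

Per (individual, site) cell over the four seasons: the coefficient of
variation (sample sd / mean) of each top genus's relative abundance and of
Shannon diversity, plus the per-individual mean-sd correlation of genus
abundances.  Shannon diversity uses the plug-in estimator in nats; it is
isolated behind :func:`shannon` so a richness-corrected estimator could be
swapped in without touching the CV machinery.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import SampleMetadata
from .preprocess import RelAbundanceTable
from .stats_core import bh_adjust, spearman

__all__ = [
    "shannon",
    "shannon_per_sample",
    "cv",
    "cv_profiles",
    "mean_sd_correlation",
]

logger = logging.getLogger(__name__)


def shannon(counts_for_sample) -> float:
    """Plug-in Shannon diversity H = -sum p_i ln p_i (nats) over observed taxa."""
    x = np.asarray(counts_for_sample, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no Shannon diversity")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table) -> pd.Series:
    """Shannon diversity for every sample of a count or proportion table."""
    mat = table.counts if hasattr(table, "counts") else table.fractions
    return pd.Series([shannon(mat[:, j]) for j in range(mat.shape[1])],
                     index=table.samples, name="shannon")


def cv(values) -> float:
    """Coefficient of variation: sample sd (n-1 denominator) / mean.

    Returns NaN (the "undefined" flag) when fewer than 2 values are given
    or the mean is zero.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return float("nan")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(x.std(ddof=1) / m)


def cv_profiles(genus_table: RelAbundanceTable, shannon_values: pd.Series,
                metadata: SampleMetadata, genera: list[str] | None = None):
    """CV per (individual, site, genus) and Shannon CV per (individual, site).

    Each (individual, site) cell is expected to hold one sample per season;
    cells with 2 or 3 seasons are tolerated with a warning, cells with fewer
    than 2 raise.  Returns ``(genus_cv, shannon_cv)`` DataFrames; undefined
    CVs (genus absent in all seasons) are NaN, never 0.
    """
    if genera is None:
        genera = list(genus_table.taxa)
    meta = metadata.for_samples(genus_table.samples)
    gdf = genus_table.to_frame()
    genus_rows, shannon_rows = [], []
    for (ind, site), sub in meta.groupby(["individual", "site"], sort=False):
        if sub["season"].duplicated().any():
            raise ValueError(f"duplicate season in cell ({ind}, {site})")
        n_seasons = len(sub)
        if n_seasons < 2:
            raise ValueError(
                f"cell ({ind}, {site}) has {n_seasons} season(s); need >= 2")
        if n_seasons < 4:
            logger.warning("cell (%s, %s) has only %d seasons", ind, site,
                           n_seasons)
        samples = sub.index.tolist()
        for g in genera:
            series = gdf.loc[g, samples].to_numpy(dtype=float)
            mean = series.mean()
            genus_rows.append((ind, site, g, n_seasons, mean,
                               series.std(ddof=1), cv(series)))
        hvals = shannon_values.loc[samples].to_numpy(dtype=float)
        shannon_rows.append((ind, site, n_seasons, hvals.mean(),
                             hvals.std(ddof=1), cv(hvals)))
    genus_cv = pd.DataFrame(
        genus_rows,
        columns=["individual", "site", "genus", "n_seasons", "mean", "sd", "cv"],
    )
    shannon_cv = pd.DataFrame(
        shannon_rows,
        columns=["individual", "site", "n_seasons", "mean", "sd", "cv"],
    )
    return genus_cv, shannon_cv


def mean_sd_correlation(genus_table: RelAbundanceTable,
                        metadata: SampleMetadata, n_top: int = 100) -> pd.DataFrame:
    """Per individual: Spearman correlation between each genus's temporal
    mean relative abundance and its temporal sd, over the ``n_top`` most
    abundant genera; BH-adjusted across individuals."""
    meta = metadata.for_samples(genus_table.samples)
    gdf = genus_table.to_frame()
    overall = gdf.mean(axis=1).sort_values(ascending=False)
    top = overall.index[:n_top].tolist()
    rows = []
    for ind, sub in meta.groupby("individual", sort=False):
        block = gdf.loc[top, sub.index.tolist()]
        means = block.mean(axis=1).to_numpy()
        sds = block.std(axis=1, ddof=1).to_numpy()
        ok = ~np.isnan(sds)
        if ok.sum() < 3:
            raise ValueError(f"individual {ind!r} has < 3 genera with defined "
                             "mean and sd")
        res = spearman(means[ok], sds[ok])
        rows.append((ind, int(ok.sum()), res.statistic, res.p_value,
                     res.undefined))
    df = pd.DataFrame(rows, columns=["individual", "n_genera", "rho", "p",
                                     "undefined"])
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
    return df
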