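"""Preprocessing chain for untargeted-metabolomics intensity tables.

The canonical order, enforced through the table's state flag, is

    raw -> impute_half_min -> total_quantity_normalize -> log2_transform
        -> (autoscale | covariate_adjust)

Half-minimum imputation replaces non-detects by half the smallest observed
intensity of that metabolite (a left-censoring assumption).  Total-quantity
normalization divides each sample by its total signal, then rescales by the
mean raw total so magnitudes remain interpretable (the global constant
cancels after log2 and centering).  Autoscaling and covariate adjustment are
terminal, mutually exclusive steps: autoscaled profiles feed the variance
diagnostics, covariate-adjusted residuals feed differential testing and
classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DatasetError, IntensityTable


def impute_half_min(table: IntensityTable) -> IntensityTable:
    """Replace each missing cell by half the metabolite's minimum observed value."""
    table.require_state("raw")
    values = table.values.copy()
    all_missing = values.columns[values.isna().all(axis=0)]
    if len(all_missing):
        raise DatasetError(f"metabolite(s) with no observed values: {list(all_missing)}")
    fill = values.min(axis=0, skipna=True) / 2.0
    values = values.fillna(fill)
    return table.with_values(values, state="imputed")


def total_quantity_normalize(table: IntensityTable) -> IntensityTable:
    """Scale each sample to the mean total signal across samples.

    Each sample's values are divided by its own total and multiplied by the
    mean total, so all row sums are equal afterwards and the overall
    magnitude is preserved.  Idempotent.
    """
    table.require_state("imputed", "normalized")
    values = table.values
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise DatasetError(f"sample(s) with non-positive total signal: {bad}")
    scaled = values.div(totals, axis=0) * totals.mean()
    return table.with_values(scaled, state="normalized")


def log2_transform(table: IntensityTable) -> IntensityTable:
    """Elementwise log2 to correct for non-homogeneity of variance."""
    table.require_state("normalized")
    values = table.values
    if (values <= 0).any().any():
        col = values.columns[(values <= 0).any(axis=0)][0]
        raise DatasetError(f"non-positive value in metabolite {col!r}; log2 undefined")
    return table.with_values(np.log2(values), state="logged")


def autoscale(table: IntensityTable, *, ddof: int = 1) -> IntensityTable:
    """Center each metabolite to mean 0 and scale to unit (n-1) standard deviation.

    Zero-variance metabolites are centered only and recorded in the table's
    ``zero_variance`` flag.
    """
    table.require_state("logged")
    values = table.values
    centered = values - values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    flat = sd.index[sd == 0.0]
    sd = sd.replace(0.0, 1.0)
    if len(flat):
        warnings.warn(f"zero-variance metabolite(s) centered but not scaled: {list(flat)}")
    return table.with_values(centered / sd, state="autoscaled", zero_variance=tuple(flat))


def _design_matrix(
    meta: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept plus 0/1 indicators (first-seen level as reference) or numeric columns."""
    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates:
        if cov not in meta.columns:
            raise DatasetError(f"covariate {cov!r} not in sample metadata")
        series = meta[cov]
        if pd.api.types.is_numeric_dtype(series):
            if series.nunique() <= 1:
                warnings.warn(f"covariate {cov!r} is constant; dropped from design")
                continue
            cols.append(series.to_numpy(float))
            names.append(cov)
        else:
            levels = list(dict.fromkeys(series.astype(str)))  # first-seen order
            if len(levels) <= 1:
                warnings.warn(f"covariate {cov!r} has a single level; dropped from design")
                continue
            for lev in levels[1:]:
                cols.append((series.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), names


def covariate_adjust(table: IntensityTable, covariates: Sequence[str]) -> IntensityTable:
    """Replace each metabolite by OLS residuals on intercept + encoded covariates.

    Categorical covariates are indicator-encoded with the first-seen level as
    reference.  Rank-deficient designs fall back to the least-norm solution
    with a warning.
    """
    table.require_state("logged", "autoscaled")
    X, names = _design_matrix(table.sample_meta, covariates)
    Y = table.values.to_numpy(float)
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient covariate design (rank {rank} < {X.shape[1]}); "
            "least-norm solution used"
        )
    resid = Y - X @ beta
    values = pd.DataFrame(resid, index=table.values.index, columns=table.values.columns)
    return table.with_values(values, state="covariate_adjusted")


@dataclass(frozen=True)
class VarianceDecomposition:
    """Between/within-group sum-of-squares decomposition of a profile matrix."""

    bss: float
    wss: float

    @property
    def tss(self) -> float:
        return self.bss + self.wss

    @property
    def ratio(self) -> float:
        """BSS / (BSS + WSS): fraction of variation explained by the grouping."""
        total = self.tss
        return 0.0 if total == 0.0 else self.bss / total


def variance_decomposition(
    table: IntensityTable, grouping: Sequence | str | None = None
) -> VarianceDecomposition:
    """Decompose total profile variation into between- and within-group parts.

    BSS = sum_g n_g ||xbar_g - xbar||^2, WSS = sum_g sum_{i in g}
    ||x_i - xbar_g||^2; their sum equals the total sum of squares about the
    grand mean.  ``grouping`` is a label vector, a metadata column name, or
    None for the trait label.
    """
    table.require_state("autoscaled")
    if grouping is None:
        grouping = table.trait
    if isinstance(grouping, str):
        labels = table.sample_meta[grouping].astype(str).to_numpy()
    else:
        labels = np.asarray([str(g) for g in grouping])
        if labels.shape[0] != table.n_samples:
            raise DatasetError("grouping length does not match number of samples")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise DatasetError("variance decomposition requires at least 2 groups")
    X = table.values.to_numpy(float)
    grand = X.mean(axis=0)
    bss = 0.0
    wss = 0.0
    for g in groups:
        Xg = X[labels == g]
        mu = Xg.mean(axis=0)
        bss += Xg.shape[0] * float(np.sum((mu - grand) ** 2))
        wss += float(np.sum((Xg - mu) ** 2))
    return VarianceDecomposition(bss=bss, wss=wss)
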