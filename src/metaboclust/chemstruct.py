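"""Fingerprint featurization and structure dissimilarity.

Metabolites are encoded as 166-bit MACCS structural keys.  Highly redundant
keys are removed by a deterministic greedy Pearson-correlation filter
(|r| > 0.9 by default; constant keys are dropped first since r is undefined
for them, and the lower-numbered key of a violating pair is kept).  Chemical
dissimilarity is the Soergel distance, 1 - |intersection| / |union| of the
bit sets, equal to one minus the Tanimoto similarity and a true metric on
binary vectors.  A correlation-based profile distance (1 - |Spearman rho|)
is provided as the structure-free alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DatasetError, IntensityTable, StructureSet, N_MACCS_KEYS


@dataclass
class FingerprintMatrix:
    """Binary metabolite x key matrix with the original MACCS key numbers."""

    ids: list[str]
    bits: np.ndarray  # (n_metabolites, n_keys) uint8
    key_indices: np.ndarray  # original MACCS key numbers (1-based), strictly increasing

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        self.key_indices = np.asarray(self.key_indices, dtype=int)
        if self.bits.shape != (len(self.ids), self.key_indices.size):
            raise DatasetError("fingerprint matrix shape does not match ids/key_indices")
        if not np.isin(self.bits, (0, 1)).all():
            raise DatasetError("fingerprint matrix must be binary")
        if np.any(np.diff(self.key_indices) <= 0):
            raise DatasetError("key_indices must be strictly increasing")

    @property
    def n_keys(self) -> int:
        return int(self.key_indices.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.bits,
            index=pd.Index(self.ids, name="metabolite_id"),
            columns=[f"maccs_{k}" for k in self.key_indices],
        )


@dataclass
class DistanceMatrix:
    """Symmetric metabolite x metabolite dissimilarity matrix."""

    ids: list[str]
    d: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DatasetError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DatasetError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise DatasetError("distance matrix diagonal is not zero")

    def restrict(self, ids: Sequence[str]) -> "DistanceMatrix":
        index = {m: i for i, m in enumerate(self.ids)}
        missing = [m for m in ids if m not in index]
        if missing:
            raise DatasetError(f"ids not in distance matrix: {missing}")
        idx = np.asarray([index[m] for m in ids])
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)], self.metric_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="metabolite_id")

    @classmethod
    def load(cls, path: str | Path, metric_name: str = "unknown") -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(list(frame.index.astype(str)), frame.to_numpy(float), metric_name)


def maccs_fingerprints(structures: StructureSet, *, ignore_rejects: bool = False) -> FingerprintMatrix:
    """One 166-key binary vector per metabolite.

    Structures that failed to parse must be resolved upstream; their presence
    is an error unless ``ignore_rejects`` is set.
    """
    if structures.rejects and not ignore_rejects:
        raise DatasetError(
            f"unparsed structures present: {[mid for mid, _ in structures.rejects]}"
        )
    if not structures.entries:
        raise DatasetError("empty structure set")
    ids = structures.ids
    bits = np.vstack([structures.entries[m].fingerprint for m in ids])
    return FingerprintMatrix(ids=ids, bits=bits, key_indices=np.arange(1, N_MACCS_KEYS + 1))


def _pearson_binary(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom)


def filter_correlated_bits(fp: FingerprintMatrix, cutoff: float = 0.9) -> FingerprintMatrix:
    """Drop constant keys, then greedily remove keys correlated with a kept one.

    Keys are scanned in ascending key order; a key is removed when its
    |Pearson r| with any previously retained key exceeds ``cutoff`` (so the
    lower-numbered key of a violating pair survives).  Deterministic.
    """
    if len(fp.ids) < 2:
        raise DatasetError("bit filtering requires at least 2 metabolites")
    B = fp.bits.astype(float)
    variable = [j for j in range(fp.n_keys) if 0 < B[:, j].sum() < len(fp.ids)]
    kept: list[int] = []
    for j in variable:
        if all(abs(_pearson_binary(B[:, j], B[:, k])) <= cutoff for k in kept):
            kept.append(j)
    if not kept:
        raise DatasetError("all fingerprint keys removed by the correlation filter")
    return FingerprintMatrix(
        ids=fp.ids, bits=fp.bits[:, kept], key_indices=fp.key_indices[kept]
    )


def soergel_distance(fp: FingerprintMatrix) -> DistanceMatrix:
    """Soergel (1 - Tanimoto) distance between fingerprint rows.

    d(i, j) = 1 - |b_i AND b_j| / |b_i OR b_j|; a pair of all-zero vectors is
    assigned d = 0 by convention (the 0/0 Tanimoto is undefined).
    """
    if len(fp.ids) < 2:
        raise DatasetError("distance computation requires at least 2 metabolites")
    B = fp.bits.astype(np.int64)
    inter = B @ B.T
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(fp.ids), d=d, metric_name="soergel")


def correlation_distance(table: IntensityTable, method: str = "spearman") -> DistanceMatrix:
    """Profile distance 1 - |Spearman rho| between metabolite columns.

    Zero-variance profiles get correlation 0 (distance 1) with a warning.
    """
    if method != "spearman":
        raise DatasetError(f"unsupported correlation method {method!r}")
    if table.n_samples < 3:
        raise DatasetError("correlation distance requires at least 3 samples")
    X = table.values.to_numpy(float)
    sd = X.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # spearmanr warns on constant input
        rho = stats.spearmanr(X).statistic
    rho = np.asarray(rho, float)
    if rho.ndim == 0:  # spearmanr collapses the 2-column case to a scalar
        r = float(np.nan_to_num(rho))
        rho = np.array([[1.0, r], [r, 1.0]])
    if flat.size:
        warnings.warn(
            f"zero-variance profile(s) assigned correlation 0: "
            f"{[table.metabolites[j] for j in flat]}"
        )
        rho[flat, :] = 0.0
        rho[:, flat] = 0.0
    d = 1.0 - np.abs(rho)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=table.metabolites, d=d, metric_name="spearman")
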