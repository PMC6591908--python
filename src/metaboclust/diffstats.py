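"""Permutation-based differential analysis and enrichment statistics.

Differential testing uses an unpaired Welch t statistic on covariate-adjusted
residuals with a Monte-Carlo permutation null: trait labels are shuffled
uniformly at random and the two-sided p-value follows the add-one convention
p = (1 + #{|t*| >= |t_obs|}) / (n_perm + 1), which is a valid Monte-Carlo
p-value (never zero).  Benjamini-Hochberg step-up q-values control the false
discovery rate; the default significance threshold is q <= 0.075.

Enrichment statistics cover one-sided Fisher exact tests for
over-representation of significant metabolites (or pathway members) inside a
structure cluster, and the upper-tail hypergeometric over-representation
test for pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DatasetError, IntensityTable, PathwayAnnotation

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .cluster import ClusterAssignment


# -- permutation t-test --------------------------------------------------------


def _welch_t(
    sum_a: np.ndarray, sq_a: np.ndarray, n_a: int,
    sum_b: np.ndarray, sq_b: np.ndarray, n_b: int,
) -> np.ndarray:
    """Welch t from per-group sums and sums of squares (inputs pre-centered).

    Zero pooled variance is resolved by convention: t = 0 when the mean
    difference is also zero, +/- inf otherwise.
    """
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    var_a = np.maximum(sq_a - n_a * mean_a**2, 0.0) / (n_a - 1)
    var_b = np.maximum(sq_b - n_b * mean_b**2, 0.0) / (n_b - 1)
    diff = mean_a - mean_b
    denom = np.sqrt(var_a / n_a + var_b / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(denom == 0.0, np.where(diff == 0.0, 0.0, np.inf * np.sign(diff)), t)
    return t


def _permutation_pvalue(
    pooled: np.ndarray, n_a: int, n_perm: int, t_obs: float, rng: np.random.Generator,
    batch: int = 20000,
) -> float:
    """Two-sided permutation p for a single metabolite; labels shuffled uniformly.

    Permutations are drawn over the sorted pooled multiset and always select
    the positions of the smaller group, so the p-value is exactly invariant
    to swapping the group labels (|t| only depends on the bipartition).
    """
    n = pooled.size
    vals = np.sort(pooled)
    n_sel = min(n_a, n - n_a)
    total = vals.sum()
    total_sq = (vals**2).sum()
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)[:, :n_sel]
        take = vals[idx]
        sum_a = take.sum(axis=1)
        sq_a = (take**2).sum(axis=1)
        t_star = _welch_t(sum_a, sq_a, n_sel, total - sum_a, total_sq - sq_a, n - n_sel)
        exceed += int(np.count_nonzero(np.abs(t_star) >= abs(t_obs)))
        done += b
    return (1 + exceed) / (n_perm + 1)


def permutation_t_test(
    x: Sequence[float], y: Sequence[float], n_perm: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Unpaired Welch t with a Monte-Carlo permutation two-sided p-value.

    Returns ``(statistic, p_value)`` with the add-one convention
    p = (1 + #{|t*| >= |t_obs|}) / (n_perm + 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise DatasetError("permutation t-test requires at least 2 values per group")
    pooled = np.concatenate([x, y])
    pooled = pooled - pooled.mean()  # shift-invariant; avoids cancellation
    t_obs = float(
        _welch_t(
            np.array([pooled[: x.size].sum()]), np.array([(pooled[: x.size] ** 2).sum()]), x.size,
            np.array([pooled[x.size:].sum()]), np.array([(pooled[x.size:] ** 2).sum()]), y.size,
        )[0]
    )
    rng = np.random.default_rng(seed)
    p = _permutation_pvalue(pooled, x.size, n_perm, t_obs, rng)
    return t_obs, p


# -- multiple testing ----------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise DatasetError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# -- per-metabolite differential analysis --------------------------------------


@dataclass
class DifferentialResult:
    """Per-metabolite differential statistics for a binary trait.

    ``frame`` is indexed by metabolite id with columns ``mean_log_fc``
    (case mean minus control mean of the tested values, log2 scale when the
    input is log-scale), ``fold_change`` (back-transformed, for display),
    ``t_stat``, ``p_value``, ``q_value``, and ``significant``.
    """

    frame: pd.DataFrame
    fdr: float
    n_permutations: int
    seed: int

    @property
    def significant_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["significant"]])

    def significance_map(self) -> dict[str, bool]:
        return dict(zip(self.frame.index, self.frame["significant"].astype(bool)))


def differential_analysis(
    table: IntensityTable,
    fdr: float = 0.075,
    n_perm: int = 100_000,
    seed: int = 0,
    *,
    display_table: IntensityTable | None = None,
) -> DifferentialResult:
    """Permutation t-test per metabolite with BH correction.

    ``table`` should hold covariate-adjusted residuals (states ``logged``
    and ``autoscaled`` are also accepted for covariate-free designs).  Each
    metabolite gets an independent permutation stream spawned from ``seed``,
    so p-values are mutually independent under the null and the result is
    reproducible bit for bit.  ``display_table`` (state ``normalized``) may
    supply the back-transformed means used for the display fold change.
    """
    table.require_state("logged", "autoscaled", "covariate_adjusted")
    if not 0 < fdr < 1:
        raise DatasetError("fdr must lie in (0, 1)")
    labels = table.labels01()
    n_case = int(labels.sum())
    n_ctrl = int(labels.size - n_case)
    if n_case < 2 or n_ctrl < 2:
        raise DatasetError("differential analysis requires >= 2 samples per trait group")
    X = table.values.to_numpy(float)
    case_mask = labels == 1
    children = np.random.SeedSequence(seed).spawn(X.shape[1])
    stats_t = np.empty(X.shape[1])
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        pooled = np.concatenate([col[case_mask], col[~case_mask]])
        pooled = pooled - pooled.mean()
        t_obs = float(
            _welch_t(
                np.array([pooled[:n_case].sum()]), np.array([(pooled[:n_case] ** 2).sum()]), n_case,
                np.array([pooled[n_case:].sum()]), np.array([(pooled[n_case:] ** 2).sum()]), n_ctrl,
            )[0]
        )
        rng = np.random.default_rng(children[j])
        stats_t[j] = t_obs
        pvals[j] = _permutation_pvalue(pooled, n_case, n_perm, t_obs, rng)
    qvals = bh_adjust(pvals)
    mean_diff = X[case_mask].mean(axis=0) - X[~case_mask].mean(axis=0)
    if display_table is not None:
        display_table.require_state("normalized")
        D = display_table.values.loc[table.samples, table.metabolites].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = D[case_mask].mean(axis=0) / D[~case_mask].mean(axis=0)
    else:
        fold = np.exp2(mean_diff)
    frame = pd.DataFrame(
        {
            "mean_log_fc": mean_diff,
            "fold_change": fold,
            "t_stat": stats_t,
            "p_value": pvals,
            "q_value": qvals,
            "significant": qvals <= fdr,
        },
        index=pd.Index(table.metabolites, name="metabolite_id"),
    )
    return DifferentialResult(frame=frame, fdr=fdr, n_permutations=n_perm, seed=seed)


# -- enrichment tests ----------------------------------------------------------


@dataclass
class EnrichmentResult:
    """One enrichment test: a 2x2 table or hypergeometric parameters plus p/q."""

    unit_id: str
    counts: tuple[int, int, int, int]  # (in&hit, in&miss, out&hit, out&miss) or (N, K, n, k)
    p_value: float
    q_value: float | None = None
    significant: bool | None = None


def _flags_for(ids: Sequence[str], flags) -> np.ndarray:
    if isinstance(flags, Mapping):
        return np.asarray([bool(flags[i]) for i in ids])
    arr = np.asarray(flags, bool)
    if arr.shape[0] != len(ids):
        raise DatasetError("flag vector length does not match number of metabolites")
    return arr


def _fisher_per_cluster(
    clusters: "ClusterAssignment", hit: np.ndarray, what: str
) -> list[EnrichmentResult]:
    results = []
    for lab in sorted(set(clusters.labels)):
        in_cluster = np.asarray(clusters.labels) == lab
        if in_cluster.all():
            warnings.warn(f"cluster {lab} covers the whole population; p = 1")
            a, b = int(hit[in_cluster].sum()), int((~hit[in_cluster]).sum())
            results.append(EnrichmentResult(str(lab), (a, b, 0, 0), 1.0))
            continue
        a = int((in_cluster & hit).sum())
        b = int((in_cluster & ~hit).sum())
        c = int((~in_cluster & hit).sum())
        d = int((~in_cluster & ~hit).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        results.append(EnrichmentResult(str(lab), (a, b, c, d), float(p)))
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def fisher_cluster_enrichment(
    clusters: "ClusterAssignment", significant
) -> list[EnrichmentResult]:
    """One-sided Fisher exact test per cluster for over-representation of
    significant metabolites, with BH correction across clusters.

    ``significant`` is a boolean vector aligned to ``clusters.ids`` or a
    mapping metabolite_id -> bool.
    """
    hit = _flags_for(clusters.ids, significant)
    return _fisher_per_cluster(clusters, hit, "significant")


def fisher_pathway_in_cluster(
    clusters: "ClusterAssignment", pathway_members: frozenset[str] | set[str]
) -> list[EnrichmentResult]:
    """Same contract as :func:`fisher_cluster_enrichment` with pathway
    membership in place of significance."""
    hit = np.asarray([i in pathway_members for i in clusters.ids])
    return _fisher_per_cluster(clusters, hit, "pathway membership")


def pathway_enrichment(
    annotation: PathwayAnnotation,
    significant_set: set[str],
    population: Sequence[str],
    fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test per pathway.

    With population size N, K pathway members in the population, n
    significant metabolites drawn and overlap k, p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  BH correction across pathways; significant at
    q <= fdr.
    """
    population = list(population)
    pop = set(population)
    if len(pop) != len(population):
        raise DatasetError("population contains duplicate ids")
    sig = set(significant_set)
    if not sig <= pop:
        raise DatasetError("significant_set must be a subset of the population")
    N, n = len(pop), len(sig)
    results = []
    for pid, (_, members) in annotation.pathways.items():
        inpop = members & pop
        if not inpop:
            warnings.warn(f"pathway {pid!r} has no members in the population; skipped")
            continue
        K = len(inpop)
        k = len(inpop & sig)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(pid, (N, K, n, k), min(p, 1.0)))
    if results:
        q = bh_adjust([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.significant = bool(qv <= fdr)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "unit_id": r.unit_id,
            "count_a": r.counts[0],
            "count_b": r.counts[1],
            "count_c": r.counts[2],
            "count_d": r.counts[3],
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
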