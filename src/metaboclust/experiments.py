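"""Seeded simulation experiments exercising the full analysis chain.

These are the package's built-in calibration and recovery studies: null
calibration of the permutation test, realized false-discovery proportion
under the null, recovery of a planted chemically coherent metabolite module,
and the head-to-head comparison of the LOOCV-selected cluster classifier
against the best single-metabolite classifier on a batch-shifted external
cohort.  Problem sizes follow the generator defaults (40 cases / 40 controls
per cohort, the full 70-metabolite structure library) with permutation
counts chosen per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .chemstruct import filter_correlated_bits, maccs_fingerprints, soergel_distance
from .classify import (
    ClassifierSpec,
    external_validate,
    grid_search,
    select_best,
    train_final,
)
from .cluster import ClusterAssignment, cluster_significant
from .diffstats import DifferentialResult, differential_analysis
from .io import IntensityTable
from .preprocess import (
    covariate_adjust,
    impute_half_min,
    log2_transform,
    total_quantity_normalize,
)
from .synthdata import (
    SimulationConfig,
    SimulationTruth,
    family_recovery_ari,
    significant_recall,
    simulate_cohort_pair,
)

COVARIATES = ("gender", "smoking")


def preprocess_for_analysis(
    table: IntensityTable, covariates: Sequence[str] = COVARIATES
) -> tuple[IntensityTable, IntensityTable]:
    """Impute, normalize, log2, covariate-adjust; returns (adjusted, normalized)."""
    normalized = total_quantity_normalize(impute_half_min(table))
    logged = log2_transform(normalized)
    return covariate_adjust(logged, list(covariates)), normalized


# -- null calibration and FDR --------------------------------------------------


def null_calibration(
    seed: int,
    n_metabolites: int = 1000,
    n_perm: int = 999,
    alpha: float = 0.05,
) -> float:
    """Fraction of null permutation p-values at or below ``alpha``.

    Simulates a no-effect cohort (the panel padded with structure-free null
    metabolites up to ``n_metabolites``), runs the standard preprocessing and
    per-metabolite permutation tests, and returns the empirical rejection
    rate, which should match ``alpha``.
    """
    cfg = SimulationConfig(seed=seed, signal_spec=())
    n_structured = len(sample_panel_size(cfg))
    cfg = replace(cfg, n_unstructured=max(n_metabolites - n_structured, 0))
    train, _, _ = simulate_cohort_pair(cfg)
    adjusted, _ = preprocess_for_analysis(train)
    diff = differential_analysis(adjusted, n_perm=n_perm, seed=seed)
    p = diff.frame["p_value"].to_numpy()
    return float(np.mean(p <= alpha))


def sample_panel_size(cfg: SimulationConfig) -> list[str]:
    from .synthdata import sample_structures

    structures, _ = sample_structures(cfg)
    return structures.ids


def null_fdp(
    seeds: Sequence[int],
    n_metabolites: int = 100,
    n_perm: int = 999,
    fdr: float = 0.075,
) -> list[float]:
    """Realized false-discovery proportion per seeded null simulation.

    Every metabolite is null, so the FDP of a simulation is 1 when anything
    is flagged and 0 otherwise; the mean over seeds estimates the attained
    FDR, bounded by the nominal level for independent tests.
    """
    out = []
    for seed in seeds:
        cfg = SimulationConfig(seed=seed, signal_spec=())
        n_structured = len(sample_panel_size(cfg))
        cfg = replace(cfg, n_unstructured=max(n_metabolites - n_structured, 0))
        train, _, _ = simulate_cohort_pair(cfg)
        adjusted, _ = preprocess_for_analysis(train)
        diff = differential_analysis(adjusted, fdr=fdr, n_perm=n_perm, seed=seed)
        n_flagged = int(diff.frame["significant"].sum())
        out.append(1.0 if n_flagged > 0 else 0.0)
    return out


# -- planted-signal discovery --------------------------------------------------


@dataclass
class DiscoveryRun:
    """Intermediate artifacts of one planted-signal discovery pass."""

    train: IntensityTable
    test: IntensityTable
    truth: SimulationTruth
    adjusted_train: IntensityTable
    diff: DifferentialResult
    significant_structured: list[str]
    clusters: ClusterAssignment | None


def run_discovery(
    seed: int,
    n_perm: int = 4999,
    config: SimulationConfig | None = None,
    bit_cutoff: float = 0.9,
) -> DiscoveryRun:
    """Simulate, preprocess, test, and cluster the significant metabolites."""
    cfg = replace(config, seed=seed) if config is not None else SimulationConfig(seed=seed)
    train, test, truth = simulate_cohort_pair(cfg)
    adjusted, _ = preprocess_for_analysis(train)
    diff = differential_analysis(adjusted, n_perm=n_perm, seed=seed)
    sig = [m for m in diff.significant_ids if m in truth.structures]
    clusters = None
    if len(sig) >= 2:
        fp = filter_correlated_bits(maccs_fingerprints(truth.structures), bit_cutoff)
        dm = soergel_distance(fp).restrict(sig)
        clusters = cluster_significant(dm)
    return DiscoveryRun(
        train=train, test=test, truth=truth, adjusted_train=adjusted,
        diff=diff, significant_structured=sig, clusters=clusters,
    )


def planted_recovery(seed: int, n_perm: int = 4999) -> dict:
    """Recall of the planted signal and ARI of the recovered chemical module."""
    run = run_discovery(seed, n_perm=n_perm)
    recall = significant_recall(run.diff.significant_ids, run.truth)
    aris = {}
    for fam in run.truth.planted_modules:
        aris[fam] = (
            family_recovery_ari(run.clusters, run.truth, fam)
            if run.clusters is not None
            else 0.0
        )
    return {
        "recall": recall,
        "module_ari": min(aris.values()) if aris else float("nan"),
        "n_significant": len(run.diff.significant_ids),
        "recovered": recall == 1.0 and aris and min(aris.values()) == 1.0,
    }


def cluster_vs_single(
    seed: int,
    n_perm: int = 4999,
    families: Sequence[str] = ("svm",),
) -> dict:
    """External accuracy of the LOOCV-selected cluster model vs the best single.

    Both model groups are selected by LOOCV accuracy on the training cohort
    only, refitted on all training samples, and evaluated with their frozen
    thresholds on the independently simulated, batch-shifted test cohort
    (preprocessed with its own normalization and covariate adjustment).
    """
    run = run_discovery(seed, n_perm=n_perm)
    adjusted_test, _ = preprocess_for_analysis(run.test)
    out = {
        "n_significant": len(run.significant_structured),
        "single_external_accuracy": float("nan"),
        "cluster_external_accuracy": float("nan"),
        "cluster_wins": False,
    }
    if not run.significant_structured:
        return out
    single_reports = [
        grid_search(
            run.adjusted_train,
            ClassifierSpec((m,), "logistic", seed=seed),
            name=f"single:{m}",
        )
        for m in run.significant_structured
    ]
    best_single = select_best(single_reports)
    model = train_final(run.adjusted_train, best_single.spec, best_single.chosen_hyperparameters)
    ext_single = external_validate(
        model, best_single.threshold, adjusted_test, best_single.spec.metabolite_set
    )
    out["single_external_accuracy"] = ext_single["accuracy"]
    if run.clusters is None or not run.clusters.multi_member_clusters():
        return out
    cluster_reports = []
    for lab, members in run.clusters.multi_member_clusters().items():
        for fam in families:
            cluster_reports.append(
                grid_search(
                    run.adjusted_train,
                    ClassifierSpec(tuple(members), fam, seed=seed),
                    name=f"cluster{lab}:{fam}",
                )
            )
    best_cluster = select_best(cluster_reports)
    model = train_final(
        run.adjusted_train, best_cluster.spec, best_cluster.chosen_hyperparameters
    )
    ext_cluster = external_validate(
        model, best_cluster.threshold, adjusted_test, best_cluster.spec.metabolite_set
    )
    out["cluster_external_accuracy"] = ext_cluster["accuracy"]
    out["cluster_wins"] = bool(
        ext_cluster["accuracy"] > ext_single["accuracy"]
    )
    return out
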