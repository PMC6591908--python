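"""End-to-end orchestration of the chemocentric analysis.

``run_all`` executes the stages in order — alignment and preprocessing of
the train (and optional test) tables, permutation differential analysis,
fingerprinting and Soergel distances, whole-panel and significant-subset
clustering, cluster/pathway enrichment, the classifier suite with LOOCV
model selection, and external validation — writing every intermediate
artifact plus a summary table to the output directory.  Outputs carry a
provenance header (tool version, seed, config hash) and contain no
timestamps, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chemstruct import (
    DistanceMatrix,
    filter_correlated_bits,
    maccs_fingerprints,
    soergel_distance,
)
from .classify import (
    DEFAULT_ML_FAMILIES,
    ClassifierReport,
    build_model_suite,
    select_best,
    suite_frame,
    validate_suite,
)
from .cluster import ClusterAssignment, cluster_significant, select_k
from .diffstats import (
    DifferentialResult,
    enrichment_frame,
    fisher_cluster_enrichment,
    fisher_pathway_in_cluster,
    pathway_enrichment,
)
from .io import (
    DatasetError,
    IntensityTable,
    align_dataset,
    read_intensity_table,
    read_pathways,
    read_structures,
    write_intensity_table,
)
from .preprocess import (
    covariate_adjust,
    impute_half_min,
    log2_transform,
    total_quantity_normalize,
)

log = logging.getLogger("metaboclust")


@dataclass
class PipelineConfig:
    """All file paths, thresholds and seeds for one pipeline run."""

    train_table: str
    structures: str
    test_table: str | None = None
    pathways: str | None = None
    meta_columns: tuple[str, ...] = ("status", "gender", "smoking")
    trait: str | None = None  # defaults to the first metadata column
    case_label: str | None = None
    covariates: tuple[str, ...] = ("gender", "smoking")
    fdr_diff: float = 0.075
    fdr_enrich: float = 0.05
    bit_corr_cutoff: float = 0.9
    n_perm: int = 100_000
    families: tuple[str, ...] = DEFAULT_ML_FAMILIES
    seed: int = 17
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("fdr_diff", "fdr_enrich", "bit_corr_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DatasetError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("meta_columns", "covariates", "families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    config: PipelineConfig
    diff: DifferentialResult
    clusters_all: ClusterAssignment
    clusters_significant: ClusterAssignment | None
    reports: list[ClassifierReport]
    best: ClassifierReport | None
    out_dir: Path


class PipelineError(RuntimeError):
    def __init__(self, stage: str, last_artifact: str | None, cause: Exception):
        super().__init__(
            f"stage {stage!r} failed ({cause}); last good artifact: {last_artifact or 'none'}"
        )
        self.stage = stage
        self.last_artifact = last_artifact


def _preprocess(table: IntensityTable, covariates) -> tuple[IntensityTable, IntensityTable]:
    normalized = total_quantity_normalize(impute_half_min(table))
    adjusted = covariate_adjust(log2_transform(normalized), list(covariates))
    return adjusted, normalized


def _provenance(config: PipelineConfig) -> str:
    return (
        f"# metaboclust {__version__}\n"
        f"# seed {config.seed}\n"
        f"# config_hash {config.config_hash()}\n"
    )


def _write_with_header(frame: pd.DataFrame, path: Path, header: str, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, **kw)


def run_all(config: PipelineConfig) -> PipelineReport:
    """Run every stage in order; see the module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    last_artifact: str | None = None
    stage = "read_inputs"

    def _save(frame: pd.DataFrame, name: str, **kw) -> None:
        nonlocal last_artifact
        _write_with_header(frame, out / name, header, **kw)
        last_artifact = name

    try:
        trait = config.trait or config.meta_columns[0]
        train = read_intensity_table(
            config.train_table, config.meta_columns, trait=trait,
            case_label=config.case_label,
        )
        structures = read_structures(config.structures)
        test = None
        if config.test_table:
            test = read_intensity_table(
                config.test_table, config.meta_columns, trait=trait,
                case_label=config.case_label,
            )
        if structures.rejects:
            log.warning("unparseable structures dropped: %s", [m for m, _ in structures.rejects])

        stage = "align"
        companions = [test] if test is not None else []
        train = align_dataset(train, structures, companions)
        if test is not None:
            test = align_dataset(test, structures, [train])
        panel = train.metabolites
        structures = structures.subset(panel)
        log.info("aligned panel: %d metabolites", len(panel))

        stage = "preprocess"
        adjusted_train, normalized_train = _preprocess(train, config.covariates)
        _save(pd.concat([adjusted_train.sample_meta, adjusted_train.values], axis=1),
              "adjusted_train.csv", index_label="sample_id")
        adjusted_test = None
        if test is not None:
            adjusted_test, _ = _preprocess(test, config.covariates)
            _save(pd.concat([adjusted_test.sample_meta, adjusted_test.values], axis=1),
                  "adjusted_test.csv", index_label="sample_id")

        stage = "differential_analysis"
        diff = differential_analysis_stage(
            adjusted_train, normalized_train, config
        )
        _save(diff.frame, "differential.csv")
        log.info("significant metabolites: %d / %d", len(diff.significant_ids), len(panel))

        stage = "fingerprints"
        fp = filter_correlated_bits(
            maccs_fingerprints(structures), config.bit_corr_cutoff
        )
        dm = soergel_distance(fp)
        _save(dm.to_frame(), "soergel_distance.csv", index_label="metabolite_id")

        stage = "cluster_all"
        clusters_all = select_k(dm)
        _save(clusters_all.to_frame(), "clusters_all.csv")
        if clusters_all.linkage_tree is not None:
            (out / "tree_all.nwk").write_text(
                clusters_all.linkage_tree.to_newick(clusters_all.ids) + "\n"
            )
            last_artifact = "tree_all.nwk"

        stage = "enrichment"
        enrich_clusters = fisher_cluster_enrichment(clusters_all, diff.significance_map())
        _save(enrichment_frame(enrich_clusters), "enrichment_clusters.csv", index=False)
        if config.pathways:
            annotation = read_pathways(config.pathways)
            enrich_pw = pathway_enrichment(
                annotation, set(diff.significant_ids), panel, fdr=config.fdr_enrich
            )
            _save(enrichment_frame(enrich_pw), "enrichment_pathways.csv", index=False)
            rows = []
            for r in enrich_pw:
                if not r.significant:
                    continue
                for rr in fisher_pathway_in_cluster(
                    clusters_all, annotation.members(r.unit_id)
                ):
                    row = {"pathway_id": r.unit_id, "cluster": rr.unit_id,
                           "p_value": rr.p_value, "q_value": rr.q_value}
                    rows.append(row)
            _save(pd.DataFrame(rows), "pathway_in_cluster.csv", index=False)

        stage = "cluster_significant"
        clusters_sig = None
        sig = diff.significant_ids
        if len(sig) >= 2:
            clusters_sig = cluster_significant(dm.restrict(sig))
            _save(clusters_sig.to_frame(), "clusters_significant.csv")

        stage = "classifiers"
        reports = build_model_suite(
            adjusted_train, diff,
            clusters_sig if clusters_sig is not None else _singleton_assignment(sig),
            families=config.families, seed=config.seed,
        )
        if adjusted_test is not None:
            validate_suite(reports, adjusted_test)
        _save(suite_frame(reports), "models.csv", index=False)
        best = select_best(reports) if reports else None

        stage = "summary"
        summary = suite_frame(reports)
        if best is not None:
            summary.insert(0, "selected", summary["model"] == best.name)
        _save(summary, "summary.csv", index=False)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - annotate with stage context
        raise PipelineError(stage, last_artifact, e) from e

    return PipelineReport(
        config=config, diff=diff, clusters_all=clusters_all,
        clusters_significant=clusters_sig, reports=reports, best=best, out_dir=out,
    )


def differential_analysis_stage(adjusted, normalized, config: PipelineConfig):
    from .diffstats import differential_analysis

    return differential_analysis(
        adjusted, fdr=config.fdr_diff, n_perm=config.n_perm, seed=config.seed,
        display_table=normalized,
    )


def _singleton_assignment(ids) -> ClusterAssignment:
    import numpy as np

    return ClusterAssignment(
        ids=list(ids), labels=np.arange(len(ids)), k=max(len(ids), 1) if ids else 0,
        asw=0.0, silhouettes=np.zeros(len(ids)),
    )
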