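"""Synthetic case-control metabolomics cohorts with planted chemical structure.

The generator emulates the statistical shape of untargeted GC-TOF intensity
data: per-metabolite log-normal abundances (log2 means uniform in [8, 20],
log2 SDs log-uniform in [0.3, 1.2]), trait effects expressed as mean shifts
in units of the metabolite's SD, additive covariate effects (gender, smoking)
on the log scale, left-censored non-detects (low-intensity values are the
ones that go missing), and a per-metabolite multiplicative batch bias applied
to the independently simulated test cohort.

Chemical identity comes from a bundled library of ~70 real metabolite SMILES
grouped into chemically coherent families (amino acids, sugars, organic
acids, nucleosides, fatty acids, sterols, phosphates, amines).  The default
signal plants a 2-SD shift on a 5-member fatty-acid module plus two
chemically distant singleton metabolites, mirroring the typical finding of
one structurally coherent significant cluster alongside scattered unrelated
hits.  All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DatasetError, IntensityTable, StructureSet, structures_from_pairs

#: family -> (n members with effect, effect in per-metabolite SDs, direction)
SignalSpec = tuple[str, int, float, int]

DEFAULT_SIGNAL: tuple[SignalSpec, ...] = (
    ("fatty_acids", 5, 2.0, +1),
    ("nucleosides", 1, 2.0, -1),
    ("amines", 1, 2.0, +1),
)

#: Named members carrying a family's signal (overrides the random member draw).
#: The default plants the module on saturated fatty acids, a chemically
#: homogeneous block; the unsaturated members stay null.
DEFAULT_SIGNAL_MEMBERS: Mapping[str, tuple[str, ...]] = {
    "fatty_acids": (
        "capric_acid",
        "lauric_acid",
        "myristic_acid",
        "palmitic_acid",
        "stearic_acid",
    ),
}

DEFAULT_COVARIATE_EFFECTS: Mapping[str, float] = {"gender": 0.3, "smoking": 0.3}


def load_library() -> pd.DataFrame:
    """The bundled structure library: metabolite_id, family, smiles."""
    with resources.files("metaboclust.data").joinpath("metabolite_library.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated train/test cohort pair."""

    n_case: int = 40
    n_control: int = 40
    panel: Mapping[str, int] | None = None  # family -> count; None = whole library
    n_unstructured: int = 0  # extra structure-free null metabolites
    signal_spec: tuple[SignalSpec, ...] = DEFAULT_SIGNAL
    signal_members: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_MEMBERS)
    )
    missing_rate: float = 0.1
    censor_quantile: float = 0.4
    batch_log2_sd: float = 1.0  # test-cohort bias factor is 2**N(0, sd) per metabolite
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    mu_log2_range: tuple[float, float] = (10.0, 16.0)
    sigma_log2_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise DatasetError("missing_rate must lie in [0, 1)")
        for fam, n, eff, direction in self.signal_spec:
            if not np.isfinite(eff):
                raise DatasetError(f"non-finite effect size for family {fam!r}")
            if direction not in (-1, 1):
                raise DatasetError("signal direction must be +1 or -1")
            if n < 1:
                raise DatasetError("signal member count must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated pair, sufficient for all recovery metrics."""

    structures: StructureSet
    family: dict[str, str | None]  # metabolite_id -> family (None = unstructured)
    signal_effects: dict[str, float]  # metabolite_id -> signed effect (SD units)
    planted_modules: dict[str, tuple[str, ...]]  # family -> member ids (n >= 2 signals)
    batch_shift: dict[str, float]  # metabolite_id -> multiplicative test bias
    config: SimulationConfig

    @property
    def signal_ids(self) -> tuple[str, ...]:
        return tuple(self.signal_effects)


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    panel_ss, cohort_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(panel_ss), np.random.default_rng(cohort_ss)


def sample_structures(config: SimulationConfig) -> tuple[StructureSet, dict[str, str]]:
    """Draw the metabolite panel from the bundled library, without replacement.

    Returns the structure set (ids of the form ``family__name``, so the
    family is recoverable from the id) and the id -> family map.  The draw
    depends only on the config seed.
    """
    rng, _ = _rngs(config.seed)
    lib = load_library()
    by_family = {fam: grp["metabolite_id"].tolist() for fam, grp in lib.groupby("family")}
    smiles = dict(zip(lib["metabolite_id"], lib["smiles"]))
    panel = config.panel
    if panel is None:
        panel = {fam: len(ids) for fam, ids in by_family.items()}
    pairs: list[tuple[str, str]] = []
    family: dict[str, str] = {}
    for fam in sorted(panel):
        count = panel[fam]
        if fam not in by_family:
            raise DatasetError(f"unknown structure family {fam!r}")
        pool = by_family[fam]
        if count > len(pool):
            raise DatasetError(
                f"requested {count} structures from family {fam!r} of size {len(pool)}"
            )
        chosen = [pool[i] for i in rng.choice(len(pool), size=count, replace=False)]
        for name in chosen:
            mid = f"{fam}__{name}"
            pairs.append((mid, smiles[name]))
            family[mid] = fam
    structures = structures_from_pairs(pairs)
    return structures, family


def _simulate_block(
    rng: np.random.Generator,
    n_case: int,
    n_control: int,
    mu: np.ndarray,
    sigma: np.ndarray,
    effect: np.ndarray,
    cov_beta: dict[str, np.ndarray],
    prefix: str,
) -> tuple[np.ndarray, pd.DataFrame]:
    n = n_case + n_control
    m = mu.size
    is_case = np.zeros(n, bool)
    is_case[:n_case] = True
    log2 = rng.normal(mu[None, :], sigma[None, :], size=(n, m))
    log2[is_case] += (effect * sigma)[None, :]
    meta = pd.DataFrame(
        {
            "status": np.where(is_case, "case", "control"),
            "gender": rng.choice(["F", "M"], size=n),
            "smoking": rng.choice(["never", "ever"], size=n),
        },
        index=pd.Index(
            [f"{prefix}_{'case' if c else 'ctrl'}_{i:03d}" for i, c in enumerate(is_case)],
            name="sample_id",
        ),
    )
    # covariate indicator: the lexicographically larger level carries the effect
    for cov, beta in cov_beta.items():
        x = (meta[cov] == sorted(meta[cov].unique())[-1]).to_numpy(float)
        log2 += x[:, None] * beta[None, :]
    return np.exp2(log2), meta


def _censor(
    rng: np.random.Generator, raw: np.ndarray, rate: float, censor_q: float
) -> np.ndarray:
    """Delete low-quantile values at the requested overall rate (left-censoring)."""
    if rate == 0.0:
        return raw
    out = raw.copy()
    n = raw.shape[0]
    for j in range(raw.shape[1]):
        n_miss = min(int(rng.binomial(n, rate)), n - 1)
        if n_miss == 0:
            continue
        pool = max(n_miss, int(np.ceil(censor_q * n)))
        candidates = np.argpartition(raw[:, j], pool - 1)[:pool]
        drop = rng.choice(candidates, size=n_miss, replace=False)
        out[drop, j] = np.nan
    return out


def simulate_cohort_pair(
    config: SimulationConfig,
) -> tuple[IntensityTable, IntensityTable, SimulationTruth]:
    """Simulate a training cohort, a batch-shifted test cohort, and the truth.

    Both cohorts share the metabolite panel, the per-metabolite distribution
    parameters, the trait effects and the covariate coefficients; the test
    cohort is independently sampled and multiplied by a per-metabolite batch
    bias before left-censored non-detects are introduced.
    """
    structures, family = sample_structures(config)
    _, rng = _rngs(config.seed)
    ids = structures.ids + [
        f"unstructured__m{i:04d}" for i in range(config.n_unstructured)
    ]
    fam_map: dict[str, str | None] = {**family}
    for mid in ids[len(structures.ids):]:
        fam_map[mid] = None
    m = len(ids)
    mu = rng.uniform(*config.mu_log2_range, size=m)
    lo, hi = config.sigma_log2_range
    sigma = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))

    effect = np.zeros(m)
    signal_effects: dict[str, float] = {}
    planted_modules: dict[str, tuple[str, ...]] = {}
    by_family: dict[str, list[int]] = {}
    for i, mid in enumerate(ids):
        if fam_map[mid] is not None:
            by_family.setdefault(fam_map[mid], []).append(i)
    index = {mid: i for i, mid in enumerate(ids)}
    for fam, n_sig, eff, direction in config.signal_spec:
        members = by_family.get(fam, [])
        if len(members) < n_sig:
            raise DatasetError(
                f"signal requests {n_sig} members of family {fam!r}, panel has {len(members)}"
            )
        if fam in config.signal_members:
            named = [f"{fam}__{name}" for name in config.signal_members[fam]]
            absent = [mid for mid in named if mid not in index]
            if absent:
                raise DatasetError(f"named signal members not in panel: {absent}")
            if len(named) != n_sig:
                raise DatasetError(
                    f"family {fam!r}: {len(named)} named members but n = {n_sig}"
                )
            chosen = [index[mid] for mid in named]
        else:
            chosen = members[:n_sig]  # first drawn members of the family
        # Within a module, directions alternate (substrate/product pairs move
        # oppositely); this also keeps total signal roughly trait-neutral, so
        # normalization does not manufacture trait associations elsewhere.
        for rank, i in enumerate(chosen):
            signed = direction * (1 if rank % 2 == 0 else -1) * eff
            effect[i] = signed
            signal_effects[ids[i]] = signed
        if n_sig >= 2:
            planted_modules[fam] = tuple(ids[i] for i in chosen)

    cov_beta = {
        cov: rng.normal(0.0, abs(strength) * sigma)
        for cov, strength in config.covariate_effects.items()
    }
    batch = np.exp2(rng.normal(0.0, config.batch_log2_sd, size=m))

    raw_tr, meta_tr = _simulate_block(
        rng, config.n_case, config.n_control, mu, sigma, effect, cov_beta, "tr"
    )
    raw_te, meta_te = _simulate_block(
        rng, config.n_case, config.n_control, mu, sigma, effect, cov_beta, "te"
    )
    raw_te = raw_te * batch[None, :]
    raw_tr = _censor(rng, raw_tr, config.missing_rate, config.censor_quantile)
    raw_te = _censor(rng, raw_te, config.missing_rate, config.censor_quantile)

    def _table(raw: np.ndarray, meta: pd.DataFrame) -> IntensityTable:
        values = pd.DataFrame(raw, index=meta.index, columns=ids)
        return IntensityTable(
            values=values, sample_meta=meta, trait="status", case_label="case"
        )

    truth = SimulationTruth(
        structures=structures,
        family=fam_map,
        signal_effects=signal_effects,
        planted_modules=planted_modules,
        batch_shift=dict(zip(ids, batch)),
        config=config,
    )
    return _table(raw_tr, meta_tr), _table(raw_te, meta_te), truth


# -- recovery metrics ----------------------------------------------------------


def significant_recall(significant_ids: Sequence[str], truth: SimulationTruth) -> float:
    """Fraction of planted signal metabolites flagged significant."""
    if not truth.signal_effects:
        raise DatasetError("no planted signal in this simulation")
    sig = set(significant_ids)
    return sum(mid in sig for mid in truth.signal_effects) / len(truth.signal_effects)


def family_recovery_ari(assignment, truth: SimulationTruth, fam: str) -> float:
    """ARI between the recovered module and family membership.

    The recovered module is the cluster holding the plurality of the planted
    family members (ties -> smallest label).  Both the prediction and the
    truth are binarized over the clustered ids: "in the module's cluster"
    versus "member of the planted family".  An ARI of 1 means the planted
    family forms exactly one cluster, with no foreign metabolite inside it.
    """
    from sklearn.metrics import adjusted_rand_score

    if fam not in truth.planted_modules:
        raise DatasetError(f"family {fam!r} has no planted multi-member module")
    members = set(truth.planted_modules[fam])
    labels = np.asarray(assignment.labels)
    in_truth = np.asarray([truth.family.get(mid) == fam for mid in assignment.ids])
    counts: dict[int, int] = {}
    for mid, lab in zip(assignment.ids, labels):
        if mid in members:
            counts[int(lab)] = counts.get(int(lab), 0) + 1
    if not counts:
        return 0.0
    top = max(counts.values())
    module_label = min(l for l, c in counts.items() if c == top)
    in_pred = labels == module_label
    return float(adjusted_rand_score(in_truth.astype(int), in_pred.astype(int)))
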