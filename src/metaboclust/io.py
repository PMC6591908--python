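"""Data model and file IO for the metabolomics pipeline.

The central containers are :class:`IntensityTable` (sample x metabolite
abundances plus per-sample metadata and a processing-state flag),
:class:`StructureSet` (metabolite structures with MACCS fingerprints), and
:class:`PathwayAnnotation` (pathway membership sets).  All readers accept
plain-text formats: CSV/TSV intensity matrices, two-column TSV or SDF
structure files, and GMT-like pathway files.

``metabolite_id`` is the join key across all three; matching is exact after
whitespace trimming, no fuzzy name matching is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import MACCSkeys

# RDKit writes parse diagnostics to stderr; rejects are reported through the
# StructureSet.rejects list instead.
RDLogger.DisableLog("rdApp.*")

#: Ordered processing states; each preprocessing step advances the flag.
STATES = ("raw", "imputed", "normalized", "logged", "autoscaled", "covariate_adjusted")

#: Number of MACCS structural keys (key 0 of RDKit's 167-bit vector is unused).
N_MACCS_KEYS = 166


class DatasetError(ValueError):
    """Raised for malformed or inconsistent input data."""


def _state_index(state: str) -> int:
    try:
        return STATES.index(state)
    except ValueError:
        raise DatasetError(f"unknown processing state {state!r}; expected one of {STATES}")


@dataclass
class IntensityTable:
    """A sample x metabolite abundance matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame with samples as rows and metabolites as columns.  Missing
        entries (non-detects) are NaN; they are only permitted in state
        ``raw``.
    sample_meta
        DataFrame indexed like ``values`` holding the binary trait label and
        any covariates (categorical or numeric).
    trait
        Name of the trait column in ``sample_meta``.  It must take exactly
        two levels.
    case_label
        The level of the trait treated as "case" (encoded 1).  Defaults to
        the lexicographically smallest level, which conveniently maps
        ``case < control`` and ``cancer < healthy``.
    state
        Processing state flag; see :data:`STATES`.
    zero_variance
        Metabolites flagged as zero-variance during autoscaling.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    trait: str = "status"
    case_label: str | None = None
    state: str = "raw"
    zero_variance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _state_index(self.state)
        if not self.values.index.equals(self.sample_meta.index):
            raise DatasetError("values and sample_meta must share the same sample index")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise DatasetError(f"duplicate sample_id(s): {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DatasetError(f"duplicate metabolite_id(s): {dupes}")
        if self.trait not in self.sample_meta.columns:
            raise DatasetError(f"trait column {self.trait!r} not in sample metadata")
        labels = self.sample_meta[self.trait]
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise DatasetError(f"samples without trait label: {missing}")
        levels = sorted(map(str, labels.unique()))
        if len(levels) != 2:
            raise DatasetError(f"trait must have exactly 2 levels, found {levels}")
        if self.case_label is None:
            self.case_label = levels[0]
        elif str(self.case_label) not in levels:
            raise DatasetError(f"case_label {self.case_label!r} not among trait levels {levels}")
        arr = self.values.to_numpy(dtype=float)
        if self.state == "raw":
            with np.errstate(invalid="ignore"):
                if np.nanmin(arr, initial=np.inf) < 0:
                    raise DatasetError("raw intensities must be non-negative")
        else:
            if np.isnan(arr).any():
                raise DatasetError(f"missing values are not allowed in state {self.state!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def labels01(self) -> np.ndarray:
        """Trait labels encoded case=1, control=0, in sample order."""
        return (self.sample_meta[self.trait].astype(str) == str(self.case_label)).to_numpy(int)

    def with_values(self, values: pd.DataFrame, state: str, **kw) -> "IntensityTable":
        return replace(self, values=values, state=state, **kw)

    def subset_metabolites(self, ids: Sequence[str]) -> "IntensityTable":
        missing = [m for m in ids if m not in self.values.columns]
        if missing:
            raise DatasetError(f"metabolites not in table: {missing}")
        return replace(self, values=self.values.loc[:, list(ids)])

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise DatasetError(
                f"operation requires state in {allowed}, table is {self.state!r}"
            )


@dataclass(frozen=True)
class StructureEntry:
    metabolite_id: str
    smiles: str  # canonical SMILES
    fingerprint: np.ndarray  # 166 MACCS key bits, uint8


@dataclass
class StructureSet:
    """Metabolite structures with 166-bit MACCS fingerprints.

    ``entries`` preserves insertion order; ``rejects`` records (id, smiles)
    pairs that failed to parse.
    """

    entries: dict[str, StructureEntry] = field(default_factory=dict)
    rejects: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mid, e in self.entries.items():
            if e.fingerprint.shape != (N_MACCS_KEYS,):
                raise DatasetError(f"fingerprint for {mid!r} is not {N_MACCS_KEYS} bits")

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    def __contains__(self, mid: str) -> bool:
        return mid in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, ids: Sequence[str]) -> "StructureSet":
        missing = [m for m in ids if m not in self.entries]
        if missing:
            raise DatasetError(f"structures missing for: {missing}")
        return StructureSet(entries={m: self.entries[m] for m in ids}, rejects=[])


@dataclass
class PathwayAnnotation:
    """pathway_id -> (description, member metabolite ids)."""

    pathways: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (_, members) in self.pathways.items():
            if not members:
                raise DatasetError(f"pathway {pid!r} has no members")

    def members(self, pid: str) -> frozenset[str]:
        return self.pathways[pid][1]

    def __len__(self) -> int:
        return len(self.pathways)


# -- fingerprints --------------------------------------------------------------


def maccs_bits(mol: Chem.Mol) -> np.ndarray:
    """166 MACCS key bits of a molecule (RDKit bit 0 dropped)."""
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros((167,), dtype=np.int64)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr[1:].astype(np.uint8)


def structure_entry(metabolite_id: str, smiles: str) -> StructureEntry | None:
    """Parse one SMILES; return None if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return StructureEntry(
        metabolite_id=metabolite_id,
        smiles=Chem.MolToSmiles(mol),
        fingerprint=maccs_bits(mol),
    )


def structures_from_pairs(pairs: Iterable[tuple[str, str]]) -> StructureSet:
    """Build a StructureSet from (metabolite_id, SMILES) pairs."""
    entries: dict[str, StructureEntry] = {}
    rejects: list[tuple[str, str]] = []
    for mid, smi in pairs:
        mid = str(mid).strip()
        smi = str(smi).strip()
        if mid in entries:
            raise DatasetError(f"duplicate metabolite_id in structures: {mid!r}")
        e = structure_entry(mid, smi)
        if e is None:
            rejects.append((mid, smi))
        else:
            entries[mid] = e
    if not entries:
        raise DatasetError("no parseable structures found")
    return StructureSet(entries=entries, rejects=rejects)


# -- readers / writers ---------------------------------------------------------


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_intensity_table(
    path: str | Path,
    meta_columns: Sequence[str],
    *,
    trait: str | None = None,
    case_label: str | None = None,
    sep: str | None = None,
    na_token: str = "NA",
    transpose: bool = False,
) -> IntensityTable:
    """Read a CSV/TSV intensity matrix (rows = samples by default).

    The first column holds sample ids; ``meta_columns`` name the metadata
    columns (the first is the trait unless ``trait`` is given); all remaining
    columns are metabolite abundances.  Empty cells or ``na_token`` denote
    non-detects; zeros are detected values, not missing.
    """
    path = Path(path)
    sep = _sep_for(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    names = [h.strip() for h in header[1:]]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:  # pandas would silently mangle duplicated headers
        raise DatasetError(f"duplicate column name(s) in {path.name}: {dupes}")
    raw = pd.read_csv(
        path, sep=sep, header=0, index_col=0, dtype=str,
        keep_default_na=False, skip_blank_lines=True,
    )
    if transpose:
        raw = raw.T
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    if raw.index.has_duplicates:
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise DatasetError(f"duplicate sample_id(s) in {path.name}: {dupes}")
    if raw.columns.has_duplicates:
        dupes = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise DatasetError(f"duplicate column name(s) in {path.name}: {dupes}")
    missing_meta = [c for c in meta_columns if c not in raw.columns]
    if missing_meta:
        raise DatasetError(f"metadata column(s) not found in {path.name}: {missing_meta}")
    meta = raw.loc[:, list(meta_columns)].copy()
    data = raw.drop(columns=list(meta_columns))
    values = pd.DataFrame(index=data.index, columns=data.columns, dtype=float)
    for col in data.columns:
        cell = data[col].str.strip()
        is_missing = (cell == "") | (cell == na_token)
        num = pd.to_numeric(cell.where(~is_missing), errors="coerce")
        bad = (~is_missing) & num.isna()
        if bad.any():
            row = bad.idxmax()
            raise DatasetError(
                f"non-numeric abundance in {path.name} at row {row!r}, column {col!r}: "
                f"{cell[row]!r}"
            )
        values[col] = num
    trait = trait if trait is not None else meta_columns[0]
    return IntensityTable(values=values, sample_meta=meta, trait=trait, case_label=case_label)


def write_intensity_table(table: IntensityTable, path: str | Path, *, sep: str | None = None) -> None:
    """Write the table as CSV/TSV with metadata columns before abundances."""
    path = Path(path)
    sep = _sep_for(path, sep)
    out = pd.concat([table.sample_meta, table.values], axis=1)
    out.to_csv(path, sep=sep, index=True, index_label="sample_id", na_rep="")


def read_structures(path: str | Path, *, id_property: str = "metabolite_id") -> StructureSet:
    """Read metabolite structures from a two-column TSV (id, SMILES) or SDF."""
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        pairs = []
        for mol in Chem.SDMolSupplier(str(path), sanitize=True):
            if mol is None:
                continue
            if not mol.HasProp(id_property):
                raise DatasetError(f"SDF record without {id_property!r} property in {path.name}")
            pairs.append((mol.GetProp(id_property), Chem.MolToSmiles(mol)))
        if not pairs:
            raise DatasetError(f"no parseable structures in {path.name}")
        return structures_from_pairs(pairs)
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DatasetError(f"{path.name} line {i + 1}: expected 2 tab-separated columns")
            mid, smi = fields[0].strip(), fields[1].strip()
            if i == 0 and mid.lower() in {"metabolite_id", "id", "name"}:
                continue  # header line
            pairs.append((mid, smi))
    if not pairs:
        raise DatasetError(f"no structures in {path.name}")
    return structures_from_pairs(pairs)


def write_structures(structures: StructureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in structures.entries.values():
            fh.write(f"{e.metabolite_id}\t{e.smiles}\n")


def read_pathways(path: str | Path) -> PathwayAnnotation:
    """Read a GMT-like pathway file: pathway_id <TAB> description <TAB> member ids."""
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    path = Path(path)
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise DatasetError(f"{path.name} line {i + 1}: expected pathway_id, description, members")
            pid, desc, members = fields[0], fields[1], frozenset(f for f in fields[2:] if f)
            if pid in pathways:
                raise DatasetError(f"duplicate pathway_id {pid!r} in {path.name}")
            if not members:
                raise DatasetError(f"pathway {pid!r} has no members")
            pathways[pid] = (desc, members)
    if not pathways:
        raise DatasetError(f"no pathways in {path.name}")
    return PathwayAnnotation(pathways=pathways)


# -- dataset alignment ---------------------------------------------------------


def _detected(table: IntensityTable) -> set[str]:
    """Metabolites with at least one non-missing value."""
    return set(table.values.columns[table.values.notna().any(axis=0)])


def align_dataset(
    table: IntensityTable,
    structures: StructureSet,
    companion_tables: Sequence[IntensityTable] = (),
) -> IntensityTable:
    """Restrict a raw table to the analyzable metabolite panel.

    A metabolite is retained iff it (1) has a parsed structure and (2) is
    detected in at least one sample in this table and in every companion
    table.  Order is preserved; the operation is idempotent and does not
    depend on companion order.
    """
    table.require_state("raw")
    for t in companion_tables:
        t.require_state("raw")
    keep = _detected(table)
    for t in companion_tables:
        keep &= _detected(t)
    retained = [m for m in table.metabolites if m in structures and m in keep]
    if not retained:
        raise DatasetError("no metabolites satisfy structure + detection requirements")
    return table.subset_metabolites(retained)
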