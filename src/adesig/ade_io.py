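"""Reading and writing the normalised adverse-drug-event (ADE) formats.

An ADE record is one spontaneous adverse-event report: patient demographics
(age in years, weight in kg, sex coded 0 = male / 1 = female), one or more
drug entries (name, SMILES, and a binary suspect label saying whether that
drug is flagged as the likely cause of the event), and one or more adverse
drug reaction (ADR) terms at MedDRA preferred-term (PT) level.

Records are stored as JSON-lines, one report per line, because reports are
ragged (variable drug and ADR counts). A flat CSV companion export (one row
per record-drug pair) is provided for interoperability.

MedDRA itself is a licensed dictionary, so nothing here ships MedDRA
content: the mapping from PT terms to system-organ-class (SOC) indices is
injected through a user-supplied tab-separated table (``load_soc_map``),
and all tests use synthetic vocabularies.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of MedDRA system organ classes; SOC one-hot encodings are always
#: emitted at this fixed width even when a synthetic map covers fewer.
N_SOC = 27


class FormatError(ValueError):
    """A line or file violates the documented schema."""


class MappingError(ValueError):
    """A PT term cannot be resolved, or a mapping table is inconsistent."""


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ADRTerm:
    """One PT-level adverse-reaction term with its primary SOC index."""

    pt_label: str
    soc_index: int

    def __post_init__(self):
        if not self.pt_label:
            raise FormatError("pt_label must be non-empty")
        if not 0 <= self.soc_index < N_SOC:
            raise MappingError(
                f"soc_index {self.soc_index} outside [0, {N_SOC - 1}] "
                f"for PT {self.pt_label!r}"
            )


@dataclass(frozen=True)
class DrugEntry:
    """One drug in a report: name, structure, and suspect label."""

    name: str
    smiles: str
    suspect: int

    def __post_init__(self):
        if self.suspect not in (0, 1):
            raise FormatError(f"suspect label must be 0 or 1, got {self.suspect!r}")


@dataclass(frozen=True)
class ADERecord:
    """One adverse-event report."""

    record_id: str
    age: float
    weight: float
    sex: int
    drugs: tuple[DrugEntry, ...]
    adrs: tuple[ADRTerm, ...]

    def __post_init__(self):
        if self.sex not in (0, 1):
            raise FormatError(f"sex must be 0 (male) or 1 (female), got {self.sex!r}")
        if not (np.isfinite(self.age) and self.age >= 0):
            raise FormatError(f"age must be a finite non-negative number, got {self.age!r}")
        if not (np.isfinite(self.weight) and self.weight > 0):
            raise FormatError(f"weight must be a finite positive number, got {self.weight!r}")
        if len(self.drugs) < 1:
            raise FormatError("record needs at least one drug entry")
        if len(self.adrs) < 1:
            raise FormatError("record needs at least one ADR term")


@dataclass
class SOCMap:
    """Mapping from PT label to (SOC index, SOC name)."""

    entries: dict[str, tuple[int, str]]

    @property
    def n_soc(self) -> int:
        if not self.entries:
            return 0
        return 1 + max(idx for idx, _ in self.entries.values())

    def soc_of(self, pt_label: str) -> int:
        try:
            return self.entries[pt_label][0]
        except KeyError:
            raise MappingError(f"PT term {pt_label!r} not in SOC map") from None

    def __contains__(self, pt_label: str) -> bool:
        return pt_label in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MolPropTable:
    """A molecular-property benchmark table: SMILES plus task columns.

    ``task_values`` is (n_molecules, n_tasks); NaN marks a missing label in
    multi-task classification tables.
    """

    smiles: list[str]
    task_values: np.ndarray
    task_names: list[str]
    task_kind: str  # "classification" | "regression"
    n_dropped: int = 0

    def __post_init__(self):
        if self.task_kind not in ("classification", "regression"):
            raise FormatError(f"unknown task_kind {self.task_kind!r}")
        self.task_values = np.asarray(self.task_values, dtype=np.float64)
        if self.task_values.ndim == 1:
            self.task_values = self.task_values[:, None]
        if len(self.smiles) != self.task_values.shape[0]:
            raise FormatError("smiles list and task matrix row count disagree")

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix marking observed (non-missing) labels."""
        return ~np.isnan(self.task_values)


# ----------------------------------------------------------------------
# record (de)serialisation
# ----------------------------------------------------------------------

def _record_to_obj(rec: ADERecord) -> dict:
    return {
        "record_id": rec.record_id,
        "age": rec.age,
        "weight": rec.weight,
        "sex": rec.sex,
        "drugs": [
            {"name": d.name, "smiles": d.smiles, "suspect": d.suspect}
            for d in rec.drugs
        ],
        "adrs": [{"pt": a.pt_label} for a in rec.adrs],
    }


def _obj_to_record(obj: dict, soc_map: SOCMap, lineno: int) -> ADERecord:
    try:
        drugs = tuple(
            DrugEntry(name=d["name"], smiles=d["smiles"], suspect=int(d["suspect"]))
            for d in obj["drugs"]
        )
        adrs = tuple(
            ADRTerm(pt_label=a["pt"], soc_index=soc_map.soc_of(a["pt"]))
            for a in obj["adrs"]
        )
        sex = obj["sex"]
        if sex not in (0, 1):
            raise FormatError(f"sex must be 0 or 1, got {sex!r}")
        return ADERecord(
            record_id=str(obj["record_id"]),
            age=float(obj["age"]),
            weight=float(obj["weight"]),
            sex=int(sex),
            drugs=drugs,
            adrs=adrs,
        )
    except MappingError:
        raise
    except FormatError as exc:
        raise FormatError(f"line {lineno}: {exc}") from None
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"line {lineno}: malformed record ({exc})") from None


def read_ade_records(
    path: str | Path,
    soc_map: SOCMap,
    strict: bool = False,
) -> tuple[list[ADERecord], int]:
    """Read JSON-lines ADE records, resolving every PT through ``soc_map``.

    Returns ``(records, n_dropped)``. In lenient mode (default) a record
    containing a PT absent from the map is dropped and counted; in strict
    mode it raises :class:`MappingError`. Schema violations always raise
    :class:`FormatError` with the offending line number.
    """
    path = Path(path)
    records: list[ADERecord] = []
    n_dropped = 0
    seen_ids: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"line {lineno}: not valid JSON ({exc.msg})") from None
            try:
                rec = _obj_to_record(obj, soc_map, lineno)
            except MappingError as exc:
                if strict:
                    raise MappingError(f"line {lineno}: {exc}") from None
                n_dropped += 1
                logger.debug("dropping line %d: %s", lineno, exc)
                continue
            if rec.record_id in seen_ids:
                raise FormatError(f"line {lineno}: duplicate record_id {rec.record_id!r}")
            seen_ids.add(rec.record_id)
            records.append(rec)
    if n_dropped:
        logger.info("read %d records from %s (%d dropped: unmapped PT)",
                    len(records), path, n_dropped)
    return records, n_dropped


def write_ade_records(records: list[ADERecord], path: str | Path) -> int:
    """Write records as JSON-lines; returns the number written.

    ``read_ade_records`` of the output reproduces the input field-for-field.
    """
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_obj(rec), sort_keys=True) + "\n")
    return len(records)


def export_flat_csv(records: list[ADERecord], path: str | Path) -> int:
    """Companion export: one CSV row per (record, drug) pair.

    ADR terms are joined with ``;`` in a single column. Returns row count.
    """
    path = Path(path)
    n = 0
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["record_id", "age", "weight", "sex", "drug_name", "smiles",
             "suspect", "adr_pts"]
        )
        for rec in records:
            pts = ";".join(a.pt_label for a in rec.adrs)
            for d in rec.drugs:
                writer.writerow(
                    [rec.record_id, rec.age, rec.weight, rec.sex,
                     d.name, d.smiles, d.suspect, pts]
                )
                n += 1
    return n


# ----------------------------------------------------------------------
# SOC mapping table
# ----------------------------------------------------------------------

def load_soc_map(path: str | Path) -> SOCMap:
    """Load a tab-separated ``pt_label<TAB>soc_index<TAB>soc_name`` table.

    ``#`` starts a comment line. Exact duplicate rows are de-duplicated;
    the same PT with conflicting SOC indices is a :class:`MappingError`.
    """
    path = Path(path)
    entries: dict[str, tuple[int, str]] = {}
    conflicts: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            pt, idx_s, soc_name = parts
            try:
                idx = int(idx_s)
            except ValueError:
                raise FormatError(f"line {lineno}: soc_index {idx_s!r} not an integer") from None
            if not 0 <= idx < N_SOC:
                raise MappingError(f"line {lineno}: soc_index {idx} outside [0, {N_SOC - 1}]")
            if pt in entries and entries[pt][0] != idx:
                conflicts.append(f"{pt!r}: {entries[pt][0]} vs {idx}")
                continue
            entries[pt] = (idx, soc_name)
    if conflicts:
        raise MappingError("conflicting SOC assignments: " + "; ".join(conflicts))
    return SOCMap(entries=entries)


def write_soc_map(soc_map: SOCMap, path: str | Path) -> None:
    """Write a SOC map in the TSV format ``load_soc_map`` reads."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# pt_label\tsoc_index\tsoc_name\n")
        for pt in sorted(soc_map.entries):
            idx, name = soc_map.entries[pt]
            fh.write(f"{pt}\t{idx}\t{name}\n")


# ----------------------------------------------------------------------
# molecular-property benchmark tables
# ----------------------------------------------------------------------

def read_molprop_table(path: str | Path, task_kind: str) -> MolPropTable:
    """Read a benchmark CSV: a ``smiles`` column plus one task column each.

    Empty cells are preserved as missing (NaN) for multi-task masking.
    Rows whose SMILES fails to parse are dropped and counted.
    """
    from rdkit import Chem

    df = pd.read_csv(path)
    cols_lower = {c.lower(): c for c in df.columns}
    if "smiles" not in cols_lower:
        raise FormatError("benchmark CSV needs a 'smiles' column")
    smi_col = cols_lower["smiles"]
    task_names = [c for c in df.columns if c != smi_col]
    if not task_names:
        raise FormatError("benchmark CSV needs at least one task column")

    keep_smiles: list[str] = []
    keep_rows: list[int] = []
    n_dropped = 0
    for i, smi in enumerate(df[smi_col].astype(str)):
        mol = Chem.MolFromSmiles(smi) if smi and smi != "nan" else None
        if mol is None:
            n_dropped += 1
            continue
        keep_smiles.append(smi)
        keep_rows.append(i)
    if not keep_smiles:
        raise FormatError("no valid SMILES rows in benchmark table")

    values = df.iloc[keep_rows][task_names].apply(pd.to_numeric, errors="coerce").to_numpy(
        dtype=np.float64
    )
    if task_kind == "classification":
        observed = values[~np.isnan(values)]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise FormatError("classification table has labels outside {0, 1}")
    table = MolPropTable(
        smiles=keep_smiles,
        task_values=values,
        task_names=task_names,
        task_kind=task_kind,
        n_dropped=n_dropped,
    )
    if n_dropped:
        logger.info("read %d molecules (%d invalid SMILES dropped)",
                    len(keep_smiles), n_dropped)
    return table
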