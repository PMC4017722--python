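"""Activity-table data model, CSV readers/writers, and packaged study fixtures.

The central objects are :class:`ActivityTable` (experimental IC50 values for a
set of inhibitors, the set ``P = {p_1 … p_t}``), :class:`ScoreTable` (one
prediction system's score function ``s_A``: an estimated IC50 per inhibitor),
and :class:`ScreeningRecord` (a virtual-screening candidate with an estimated
IC50 and a docking interaction energy).

Three fixtures ship with the package, transcribed from the source study of
checkpoint-kinase-2 (Chk2) inhibitors:

``table1``
    25 training-set inhibitors with experimental IC50 (2.3–100,000 nM) and
    the estimates of three pharmacophore-hypothesis generators
    (``Best_train``, ``Fast_train``, ``Caesar_train``).
``table2``
    133 testing-set inhibitors with experimental IC50 (3.4–74,000 nM) and six
    prediction systems (train-algorithm x test-algorithm: BB, BF, BC, FB, FF,
    FC).
``table3``
    21 screening candidates that survived docking, with estimated IC50 and
    CDOCKER interaction energy (kcal/mol).

Activities are stored in nM exactly as printed; nothing is rounded on ingest.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import IntegrityError, ParseError, SchemaError

__all__ = [
    "InhibitorRecord",
    "ActivityTable",
    "ScoreTable",
    "ScreeningRecord",
    "load_activity_table",
    "load_score_tables",
    "load_screening_table",
    "write_activity_table",
    "load_fixture",
    "FIXTURE_CHECKSUMS",
]


@dataclass(frozen=True)
class InhibitorRecord:
    """One inhibitor: compound id, experimental IC50 (nM), optional extras."""

    id: str
    ic50_nM: float
    smiles: str | None = None
    set_label: str | None = None  # train | test | screen

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("inhibitor id must be non-empty")
        if not self.ic50_nM > 0:
            raise ValueError(f"ic50_nM must be positive, got {self.ic50_nM!r}")


@dataclass
class ActivityTable:
    """An ordered collection of inhibitors with experimental activities.

    Ids are unique; row order is stable under read/write round-trips.
    ``units`` is fixed to nanomolar.
    """

    name: str
    records: list[InhibitorRecord] = field(default_factory=list)
    units: str = "nM"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate inhibitor ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InhibitorRecord]:
        return iter(self.records)

    @property
    def t(self) -> int:
        """Cardinality of the inhibitor set P."""
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def activities(self) -> dict[str, float]:
        return {r.id: r.ic50_nM for r in self.records}


@dataclass
class ScoreTable:
    """One prediction system's score function s_A.

    Maps each inhibitor id to an estimated biological activity in nM
    (positive). ``label`` names the system, conventionally as
    train-algorithm x test-algorithm (e.g. ``"BB"`` for Best_train/Best_test).
    """

    label: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.scores.items() if not v > 0}
        if bad:
            raise ValueError(f"scores must be positive; offending: {bad}")

    def covers(self, ids: Iterable[str]) -> list[str]:
        """Return the ids from ``ids`` missing from this table."""
        return [i for i in ids if i not in self.scores]

    def __getitem__(self, compound_id: str) -> float:
        return self.scores[compound_id]


@dataclass(frozen=True)
class ScreeningRecord:
    """A screening candidate: estimated IC50 (nM) and docking energy (kcal/mol)."""

    id: str
    est_ic50_nM: float
    energy_kcal_mol: float

    def __post_init__(self) -> None:
        if not self.est_ic50_nM > 0:
            raise ValueError(f"est_ic50_nM must be positive, got {self.est_ic50_nM!r}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {"id": "id", "ic50_nM": "ic50_nM"}


def _read_rows(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return [], []
        return list(reader.fieldnames), list(reader)


def _parse_activity(raw: str, row_index: int, column: str) -> float:
    try:
        value = float(raw.replace(",", ""))
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row_index}: column {column!r} value {raw!r} is not numeric",
            row=row_index,
        ) from None
    if not value > 0:
        raise ParseError(
            f"row {row_index}: column {column!r} value {value} is not positive",
            row=row_index,
        )
    return value


def load_activity_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    name: str | None = None,
    set_label: str | None = None,
) -> ActivityTable:
    """Read an experimental-activity CSV into an :class:`ActivityTable`.

    ``schema`` maps logical field names (``id``, ``ic50_nM``, optionally
    ``smiles``) to the file's column names. Row order is preserved; duplicate
    ids raise :class:`~qsarfusion.errors.IntegrityError`; non-positive or
    non-numeric activities raise :class:`~qsarfusion.errors.ParseError` with
    the row index.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    header, rows = _read_rows(path)
    for logical in ("id", "ic50_nM"):
        if schema[logical] not in header:
            raise SchemaError(
                f"required column {schema[logical]!r} (for {logical!r}) "
                f"not found in {path}; header is {header}"
            )
    smiles_col = schema.get("smiles")
    records = []
    for i, row in enumerate(rows):
        records.append(
            InhibitorRecord(
                id=row[schema["id"]].strip(),
                ic50_nM=_parse_activity(row[schema["ic50_nM"]], i, schema["ic50_nM"]),
                smiles=(row.get(smiles_col) if smiles_col else None),
                set_label=set_label,
            )
        )
    return ActivityTable(name=name or Path(path).stem, records=records)


def load_score_tables(
    path: str | Path,
    system_columns: list[str],
    id_column: str = "id",
) -> list[ScoreTable]:
    """Read one or more prediction systems from the columns of a CSV."""
    header, rows = _read_rows(path)
    for col in [id_column, *system_columns]:
        if col not in header:
            raise SchemaError(f"column {col!r} not found in {path}; header is {header}")
    tables = []
    for col in system_columns:
        scores = {}
        for i, row in enumerate(rows):
            scores[row[id_column].strip()] = _parse_activity(row[col], i, col)
        tables.append(ScoreTable(label=col, scores=scores))
    return tables


def load_screening_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[ScreeningRecord]:
    """Read a screening CSV (id, est_ic50_nM, energy_kcal_mol)."""
    schema = {
        "id": "id",
        "est_ic50_nM": "est_ic50_nM",
        "energy_kcal_mol": "energy_kcal_mol",
        **(schema or {}),
    }
    header, rows = _read_rows(path)
    for logical in ("id", "est_ic50_nM", "energy_kcal_mol"):
        if schema[logical] not in header:
            raise SchemaError(
                f"required column {schema[logical]!r} (for {logical!r}) not found "
                f"in {path}; header is {header}"
            )
    out = []
    for i, row in enumerate(rows):
        try:
            energy = float(row[schema["energy_kcal_mol"]])
        except (TypeError, ValueError):
            raise ParseError(
                f"row {i}: energy {row[schema['energy_kcal_mol']]!r} is not numeric",
                row=i,
            ) from None
        out.append(
            ScreeningRecord(
                id=row[schema["id"]].strip(),
                est_ic50_nM=_parse_activity(row[schema["est_ic50_nM"]], i, schema["est_ic50_nM"]),
                energy_kcal_mol=energy,
            )
        )
    return out


def write_activity_table(
    table: ActivityTable,
    path: str | Path,
    score_tables: list[ScoreTable] | None = None,
) -> None:
    """Write a table (plus optional prediction columns) as CSV.

    The written file round-trips through :func:`load_activity_table` /
    :func:`load_score_tables` reproducing ids, order, and values exactly
    (values are written with :func:`repr`-level precision).
    """
    score_tables = score_tables or []
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "ic50_nM", *[s.label for s in score_tables]])
        for rec in table.records:
            writer.writerow(
                [rec.id, repr(rec.ic50_nM), *[repr(s[rec.id]) for s in score_tables]]
            )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

#: sha256 of each packaged fixture file; locks the transcription.
FIXTURE_CHECKSUMS = {
    "table1": "7077efe35c7524d604095837f32060e0974ef21d252eb1a5ba49e04715247c2b",
    "table2": "b8881ed9395d0b2127e8fc2dbea8189e81b2fe43b6abf9c67e474bfa10c44da0",
    "table3": "bb630cebcbe379a4c523bef78468d2101c0ea2bbf6f66089063a7235289b22b0",
}

_FIXTURE_SYSTEMS = {
    "table1": ["Best_train", "Fast_train", "Caesar_train"],
    "table2": ["BB", "BF", "BC", "FB", "FF", "FC"],
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    if name not in FIXTURE_CHECKSUMS:
        raise LookupError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_CHECKSUMS)}"
        )
    return Path(str(resources.files("qsarfusion.data") / f"{name}.csv"))


def _verify_checksum(name: str, path: Path) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != FIXTURE_CHECKSUMS[name]:
        raise IntegrityError(
            f"fixture {name} checksum mismatch: expected "
            f"{FIXTURE_CHECKSUMS[name]}, got {digest}"
        )


def load_fixture(name: str):
    """Load a packaged study table.

    Returns ``(ActivityTable, list[ScoreTable])`` for ``table1`` (25
    training inhibitors, 3 systems) and ``table2`` (133 testing inhibitors,
    6 systems), or ``list[ScreeningRecord]`` for ``table3`` (21 docking
    survivors). Unknown names raise :class:`LookupError`.
    """
    path = fixture_path(name)
    _verify_checksum(name, path)
    if name == "table3":
        return load_screening_table(path)
    set_label = "train" if name == "table1" else "test"
    table = load_activity_table(path, name=name, set_label=set_label)
    systems = load_score_tables(path, _FIXTURE_SYSTEMS[name])
    return table, systems
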