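"""Core data types and table / network input-output.

Two plain-text tables drive everything:

* an interaction table, one row per observed individual bee-flower visit,
  carrying the field-measured intertegular distance (ITD, mm) of the bee and
  the maximum floral display size (FDS, mm) of the flower;
* a specimen table used to calibrate the trait regressions, one row per
  measured specimen, carrying a predictor/response pair (ITD vs proboscis
  length for bees; FDS vs nectar holder depth for plants).

Loading is total: every input row either becomes a record or is reported as
an :class:`Issue`; the two counts always reconcile with the row count.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KNOWN_INTERACTION_TYPES",
    "INTERACTION_COLUMNS",
    "SPECIMEN_COLUMNS",
    "Issue",
    "InteractionRecord",
    "SpecimenMeasurement",
    "CommunityDataset",
    "ValidationReport",
    "read_interactions",
    "read_specimens",
    "write_interactions",
    "write_specimens",
    "validate_community",
    "write_network",
    "read_network",
]

#: Interaction types with defined semantics; unknown labels are kept verbatim
#: but flagged with a warning issue.
KNOWN_INTERACTION_TYPES = frozenset(
    {"nectar", "pollen", "nectar_and_pollen", "robbing"}
)

INTERACTION_COLUMNS = (
    "record_id",
    "bee_species",
    "plant_species",
    "itd_mm",
    "fds_mm",
    "interaction_type",
    "year",
)

SPECIMEN_COLUMNS = ("side", "species", "predictor_mm", "response_mm")


@dataclass(frozen=True)
class Issue:
    """A single loading or validation finding.

    severity is one of ``"fatal"``, ``"error"`` (row rejected) or
    ``"warning"`` (row kept).
    """

    severity: str
    message: str


@dataclass(frozen=True)
class InteractionRecord:
    """One observed individual bee-flower visit with trait measurements."""

    record_id: str
    bee_species: str
    plant_species: str
    itd_mm: float
    fds_mm: float
    interaction_type: str
    year: int

    def __post_init__(self) -> None:
        if not self.itd_mm > 0:
            raise ValueError(f"itd_mm must be > 0, got {self.itd_mm!r}")
        if not self.fds_mm > 0:
            raise ValueError(f"fds_mm must be > 0, got {self.fds_mm!r}")


@dataclass(frozen=True)
class SpecimenMeasurement:
    """A calibration specimen: predictor/response trait pair in mm."""

    side: str  # "bee" or "plant"
    species: str
    predictor_mm: float
    response_mm: float

    def __post_init__(self) -> None:
        if self.side not in ("bee", "plant"):
            raise ValueError(f"side must be 'bee' or 'plant', got {self.side!r}")
        if not self.predictor_mm > 0 or not self.response_mm > 0:
            raise ValueError("specimen measurements must be positive")


@dataclass
class CommunityDataset:
    """Interactions plus calibration specimens for one community."""

    interactions: list[InteractionRecord]
    specimens: list[SpecimenMeasurement]
    #: plant species whose nectar holder depth is too short to measure; they
    #: receive the 1 mm floor instead of a regression model.
    immeasurable_plant_species: set[str] = field(default_factory=set)


@dataclass
class ValidationReport:
    n_records: int
    n_bee_species: int
    n_plant_species: int
    issues: list[Issue] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(i.severity == "fatal" for i in self.issues)


def _resolve_columns(
    fieldnames: Sequence[str],
    required: Sequence[str],
    column_map: Mapping[str, str] | None,
) -> dict[str, str]:
    """Map canonical column names to the names present in the file."""
    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    missing = []
    for name in required:
        actual = column_map.get(name, name)
        if actual not in fieldnames:
            missing.append(actual)
        else:
            resolved[name] = actual
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return resolved


def read_interactions(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[InteractionRecord], list[Issue]]:
    """Load an interaction CSV.

    Every data row becomes either a record or an ``error`` issue; unknown
    interaction types are kept with a ``warning``.  A missing required
    column is fatal and raises :class:`ValueError`.  ``column_map`` renames
    canonical columns to the headers actually present in the file.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    issues: list[Issue] = []
    seen_ids: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        cols = _resolve_columns(reader.fieldnames, INTERACTION_COLUMNS, column_map)
        for lineno, row in enumerate(reader, start=2):
            rid = (row[cols["record_id"]] or "").strip()
            try:
                itd = float(row[cols["itd_mm"]])
                fds = float(row[cols["fds_mm"]])
                year = int(float(row[cols["year"]]))
            except (TypeError, ValueError):
                issues.append(
                    Issue("error", f"line {lineno} ({rid or '?'}): non-numeric trait or year")
                )
                continue
            if rid in seen_ids:
                issues.append(Issue("error", f"line {lineno}: duplicate record_id {rid!r}"))
                continue
            itype = (row[cols["interaction_type"]] or "").strip()
            if itype not in KNOWN_INTERACTION_TYPES:
                issues.append(
                    Issue("warning", f"line {lineno} ({rid}): unknown interaction_type {itype!r}")
                )
            try:
                rec = InteractionRecord(
                    record_id=rid,
                    bee_species=row[cols["bee_species"]].strip(),
                    plant_species=row[cols["plant_species"]].strip(),
                    itd_mm=itd,
                    fds_mm=fds,
                    interaction_type=itype,
                    year=year,
                )
            except ValueError as exc:
                issues.append(Issue("error", f"line {lineno} ({rid}): {exc}"))
                continue
            seen_ids.add(rid)
            records.append(rec)
    return records, issues


def read_specimens(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SpecimenMeasurement], list[Issue]]:
    """Load a specimen-trait CSV (columns: side,species,predictor_mm,response_mm)."""
    path = Path(path)
    specimens: list[SpecimenMeasurement] = []
    issues: list[Issue] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header")
        cols = _resolve_columns(reader.fieldnames, SPECIMEN_COLUMNS, column_map)
        for lineno, row in enumerate(reader, start=2):
            try:
                spec = SpecimenMeasurement(
                    side=(row[cols["side"]] or "").strip(),
                    species=row[cols["species"]].strip(),
                    predictor_mm=float(row[cols["predictor_mm"]]),
                    response_mm=float(row[cols["response_mm"]]),
                )
            except (TypeError, ValueError) as exc:
                issues.append(Issue("error", f"line {lineno}: {exc}"))
                continue
            specimens.append(spec)
    return specimens, issues


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INTERACTION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.bee_species,
                    r.plant_species,
                    repr(r.itd_mm),
                    repr(r.fds_mm),
                    r.interaction_type,
                    r.year,
                ]
            )


def write_specimens(specimens: Iterable[SpecimenMeasurement], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPECIMEN_COLUMNS)
        for s in specimens:
            writer.writerow([s.side, s.species, repr(s.predictor_mm), repr(s.response_mm)])


def validate_community(ds: CommunityDataset) -> ValidationReport:
    """Check the structural invariants of a loaded community.

    Fatal issues: no interactions at all; a plant species with interactions
    but fewer than two calibration specimens and no 1 mm-floor flag; a bee
    side with fewer than two calibration specimens overall.
    """
    issues: list[Issue] = []
    bee_species = {r.bee_species for r in ds.interactions}
    plant_species = {r.plant_species for r in ds.interactions}
    if not ds.interactions:
        issues.append(Issue("fatal", "no interaction records"))

    plant_specimens = Counter(
        s.species for s in ds.specimens if s.side == "plant"
    )
    n_bee_specimens = sum(1 for s in ds.specimens if s.side == "bee")
    for sp in sorted(plant_species):
        if sp in ds.immeasurable_plant_species:
            continue
        if plant_specimens[sp] < 2:
            issues.append(
                Issue(
                    "fatal",
                    f"plant species {sp!r} has {plant_specimens[sp]} specimen(s), "
                    "needs >=2 or an immeasurable (1 mm floor) flag",
                )
            )
    if ds.interactions and n_bee_specimens < 2:
        issues.append(
            Issue("fatal", f"bee side has {n_bee_specimens} specimen(s), needs >=2")
        )
    return ValidationReport(
        n_records=len(ds.interactions),
        n_bee_species=len(bee_species),
        n_plant_species=len(plant_species),
        issues=issues,
    )


# ---------------------------------------------------------------------------
# network serialization


def write_network(net, path: str | Path, format: str = "json") -> None:
    """Serialize a :class:`~traitwebs.build.QuantNetwork`.

    ``matrix_csv``: plants as rows, bees as columns, labels in the header
    row/column.  ``edgelist_tsv``: one row per nonzero cell
    (plant_node, bee_node, weight).  ``json``: matrix, labels and node
    metadata — the only format that round-trips metadata.
    """
    path = Path(path)
    if format == "matrix_csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([""] + list(net.col_labels))
            for label, row in zip(net.row_labels, net.matrix):
                writer.writerow([label] + [int(v) for v in row])
    elif format == "edgelist_tsv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["plant_node", "bee_node", "weight"])
            for i, rlab in enumerate(net.row_labels):
                for j, clab in enumerate(net.col_labels):
                    w = int(net.matrix[i, j])
                    if w:
                        writer.writerow([rlab, clab, w])
    elif format == "json":
        payload = {
            "row_labels": list(net.row_labels),
            "col_labels": list(net.col_labels),
            "matrix": [[int(v) for v in row] for row in net.matrix],
            "row_meta": net.row_meta,
            "col_meta": net.col_meta,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "json"):
    """Inverse of :func:`write_network`."""
    from traitwebs.build import QuantNetwork  # local import: avoid cycle

    path = Path(path)
    if format == "matrix_csv":
        with path.open(newline="") as fh:
            rows = list(csv.reader(fh))
        col_labels = rows[0][1:]
        row_labels = [r[0] for r in rows[1:]]
        matrix = np.array([[int(v) for v in r[1:]] for r in rows[1:]], dtype=np.int64)
        return QuantNetwork(matrix=matrix, row_labels=row_labels, col_labels=col_labels)
    if format == "edgelist_tsv":
        with path.open(newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:3] != ["plant_node", "bee_node", "weight"]:
                raise ValueError("not a traitwebs edge list")
            edges = [(r[0], r[1], int(r[2])) for r in reader]
        row_labels: list[str] = []
        col_labels: list[str] = []
        for p, b, _ in edges:  # first-appearance order == row-major write order
            if p not in row_labels:
                row_labels.append(p)
            if b not in col_labels:
                col_labels.append(b)
        matrix = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
        for p, b, w in edges:
            matrix[row_labels.index(p), col_labels.index(b)] = w
        return QuantNetwork(matrix=matrix, row_labels=row_labels, col_labels=col_labels)
    if format == "json":
        payload = json.loads(path.read_text())
        return QuantNetwork(
            matrix=np.array(payload["matrix"], dtype=np.int64),
            row_labels=list(payload["row_labels"]),
            col_labels=list(payload["col_labels"]),
            row_meta=payload.get("row_meta", {}),
            col_meta=payload.get("col_meta", {}),
        )
    raise ValueError(f"unknown network format {format!r}")
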