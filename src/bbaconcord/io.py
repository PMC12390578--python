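"""Tabular readers and writers for bottle-bioassay and sentinel-cage data.

File dialect: comma-delimited UTF-8 with a header row. Bottles are stored wide
(one row per bottle, one ``t_<minutes>`` column per observation time) so the
cumulative-count monotonicity of each bottle is checkable row-by-row; cages are
one row each. Writers emit exactly the schema the readers accept, so a
write/read round trip reproduces every field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError, ValidationError
from .types import (
    STANDARD_DISTANCES,
    BottleAssay,
    ChemicalTreatment,
    FieldCageRecord,
    Grade,
    ObservationSchedule,
    StudyDataset,
)

_BOTTLE_META_COLS = ["strain", "chemical", "grade", "dose_ug", "replicate", "n"]
_CAGE_COLS = [
    "strain",
    "product",
    "distance_ft",
    "replicate",
    "is_control",
    "n",
    "dead_0h",
    "dead_05h",
    "dead_12h",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_bottle_assays(
    path: str | Path, schedule: ObservationSchedule | None = None
) -> list[BottleAssay]:
    """Read bottle records from a wide CSV; row order is preserved.

    Raises :class:`SchemaError` if a required column is absent and
    :class:`ValidationError` (naming the bottle and time) on non-monotone or
    out-of-range counts.
    """
    path = Path(path)
    schedule = schedule or ObservationSchedule.canonical()
    df = pd.read_csv(path)
    time_cols = [f"t_{t}" for t in schedule.times]
    _require_columns(df, _BOTTLE_META_COLS + time_cols, path)
    bottles = []
    for _, row in df.iterrows():
        treatment = ChemicalTreatment(
            name=str(row["chemical"]), grade=Grade(row["grade"]), dose_ug=float(row["dose_ug"])
        )
        bottles.append(
            BottleAssay(
                strain=str(row["strain"]),
                treatment=treatment,
                replicate_id=str(row["replicate"]),
                n_introduced=int(row["n"]),
                down_counts=tuple(int(row[c]) for c in time_cols),
                schedule=schedule,
            )
        )
    return bottles


def write_bottle_assays(bottles: Sequence[BottleAssay], path: str | Path) -> None:
    """Write bottle records to the wide CSV schema read_bottle_assays accepts."""
    path = Path(path)
    if not bottles:
        raise ValidationError("nothing to write: empty bottle collection")
    schedule = bottles[0].schedule
    rows = []
    for b in bottles:
        if b.schedule != schedule:
            raise ValidationError("all bottles in one file must share a schedule")
        row = {
            "strain": b.strain,
            "chemical": b.treatment.name,
            "grade": b.treatment.grade.value,
            "dose_ug": b.treatment.dose_ug,
            "replicate": b.replicate_id,
            "n": b.n_introduced,
        }
        row.update({f"t_{t}": c for t, c in zip(schedule.times, b.down_counts)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_field_cages(path: str | Path, known_distances: Sequence[int] | None = None) -> list[FieldCageRecord]:
    """Read sentinel-cage records; unknown transect distances are rejected.

    ``known_distances`` defaults to the standard 100/200/300 ft transects;
    pass an explicit sequence (or ``()`` to disable the check) for other designs.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _CAGE_COLS, path)
    if known_distances is None:
        known_distances = STANDARD_DISTANCES
    cages = []
    for _, row in df.iterrows():
        distance = int(row["distance_ft"])
        if known_distances and distance not in known_distances:
            raise ValidationError(
                f"{path}: unknown distance {distance} ft (expected one of {tuple(known_distances)})"
            )
        cages.append(
            FieldCageRecord(
                strain=str(row["strain"]),
                product=str(row["product"]),
                distance_ft=distance,
                replicate_id=str(row["replicate"]),
                n_introduced=int(row["n"]),
                dead_0h=int(row["dead_0h"]),
                dead_05h=int(row["dead_05h"]),
                dead_12h=int(row["dead_12h"]),
                is_control=bool(row["is_control"]),
            )
        )
    return cages


def write_field_cages(cages: Sequence[FieldCageRecord], path: str | Path) -> None:
    if not cages:
        raise ValidationError("nothing to write: empty cage collection")
    rows = [
        {
            "strain": c.strain,
            "product": c.product,
            "distance_ft": c.distance_ft,
            "replicate": c.replicate_id,
            "is_control": c.is_control,
            "n": c.n_introduced,
            "dead_0h": c.dead_0h,
            "dead_05h": c.dead_05h,
            "dead_12h": c.dead_12h,
        }
        for c in cages
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


@dataclass
class ValidationReport:
    """List of dataset-level violations; empty means the dataset is analyzable."""

    violations: list[str]

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.is_valid:
            return "dataset valid: no violations"
        return "\n".join(f"- {v}" for v in self.violations)


def validate_dataset(ds: StudyDataset, max_introduced: int | None = None) -> ValidationReport:
    """Check cross-record study structure; reports violations, never raises.

    Per-record invariants (monotone counts, count bounds) are enforced at
    construction; this checks what only the assembled study can know: every
    treated bottle group has a matching solvent-control group for its strain,
    schedules agree, and no analyzable unit is empty. ``max_introduced`` (e.g.
    25 for the standard protocol) optionally flags overfilled bottles.
    """
    violations: list[str] = []
    treated_strains = set()
    for b in ds.bottles:
        if b.schedule != ds.schedule:
            violations.append(
                f"bottle {b.strain}/{b.treatment.name}/{b.replicate_id}: schedule differs "
                "from the study schedule"
            )
        if b.n_introduced == 0:
            violations.append(
                f"bottle {b.strain}/{b.treatment.name}/{b.replicate_id}: 0 mosquitoes introduced"
            )
        if max_introduced is not None and b.n_introduced > max_introduced:
            violations.append(
                f"bottle {b.strain}/{b.treatment.name}/{b.replicate_id}: "
                f"{b.n_introduced} introduced exceeds protocol limit {max_introduced}"
            )
        if not b.treatment.is_control:
            treated_strains.add(b.strain)
    control_strains = {b.strain for b in ds.bottles if b.treatment.is_control}
    for strain in sorted(treated_strains - control_strains):
        violations.append(f"strain {strain}: treated bottles have no solvent-control group")
    for c in ds.cages:
        if c.n_introduced == 0:
            violations.append(
                f"cage {c.strain}/{c.product}/{c.replicate_id}: 0 mosquitoes introduced"
            )
    return ValidationReport(violations)
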