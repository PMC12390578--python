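"""Domain types for CDC bottle bioassays and sentinel-cage field trials.

The data model mirrors how these experiments are recorded in practice: one row
per bottle carrying a cumulative knockdown count at every scheduled observation
time, and one row per sentinel cage carrying cumulative dead counts at the
three check times (pre-deployment, pick-up, and 12 h post-spray). "Down" pools
knockdown and death — a mosquito unable to right itself or fly counts as down —
so a single cumulative state is tracked per time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .errors import ValidationError

#: Observation times (minutes) of the canonical 180-min assay: every 5 min for
#: the first 15 min, then every 15 min.
CANONICAL_TIMES: tuple[int, ...] = (0, 5, 10, 15, 30, 45, 60, 75, 90, 105, 120, 135, 150, 165, 180)

#: Downwind transect distances (feet) used in the sentinel-cage trial design.
STANDARD_DISTANCES: tuple[int, ...] = (100, 200, 300)


class Grade(str, Enum):
    """Insecticide grade: pure active ingredient, commercial product, or solvent blank."""

    TECHNICAL = "technical"
    FORMULATED = "formulated"
    SOLVENT_CONTROL = "solvent_control"


@dataclass(frozen=True)
class ObservationSchedule:
    """Ordered observation times, in minutes since exposure start.

    Times must be strictly increasing and start at 0 (the pre-exposure count).
    """

    times: tuple[int, ...]

    def __post_init__(self) -> None:
        times = tuple(int(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if not times:
            raise ValidationError("observation schedule is empty")
        if times[0] != 0:
            raise ValidationError(f"schedule must start at 0 min, got {times[0]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"schedule times must be strictly increasing: {times}")

    @classmethod
    def canonical(cls) -> "ObservationSchedule":
        """The standard 15-point, 180-min bottle-bioassay schedule."""
        return cls(CANONICAL_TIMES)

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(self.times)

    def index_of(self, time_min: int) -> int:
        try:
            return self.times.index(time_min)
        except ValueError:
            raise ValidationError(f"{time_min} min is not on the observation schedule") from None


@dataclass(frozen=True)
class ChemicalTreatment:
    """An insecticide treatment: name, grade, and mass applied per bottle (µg).

    Solvent controls (acetone-only bottles) carry a zero dose by definition.
    """

    name: str
    grade: Grade
    dose_ug: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grade", Grade(self.grade))
        if self.dose_ug < 0:
            raise ValidationError(f"dose must be non-negative, got {self.dose_ug}")
        if (self.dose_ug == 0) != (self.grade is Grade.SOLVENT_CONTROL):
            raise ValidationError(
                f"dose 0 is reserved for solvent controls (got {self.name!r}, "
                f"grade={self.grade.value}, dose={self.dose_ug})"
            )

    @property
    def is_control(self) -> bool:
        return self.grade is Grade.SOLVENT_CONTROL


@dataclass(frozen=True)
class BottleAssay:
    """One bottle's cumulative down/dead counts on an observation schedule."""

    strain: str
    treatment: ChemicalTreatment
    replicate_id: str
    n_introduced: int
    down_counts: tuple[int, ...]
    schedule: ObservationSchedule = field(default_factory=ObservationSchedule.canonical)

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.down_counts)
        object.__setattr__(self, "down_counts", counts)
        label = f"bottle {self.strain}/{self.treatment.name}/{self.replicate_id}"
        if self.n_introduced < 0:
            raise ValidationError(f"{label}: n_introduced must be >= 0")
        if len(counts) != len(self.schedule):
            raise ValidationError(
                f"{label}: {len(counts)} counts for {len(self.schedule)} schedule times"
            )
        for t, c in zip(self.schedule, counts):
            if c < 0 or c > self.n_introduced:
                raise ValidationError(
                    f"{label}: count {c} at t_{t} outside [0, {self.n_introduced}]"
                )
        times = self.schedule.times
        for i in range(1, len(counts)):
            if counts[i] < counts[i - 1]:
                raise ValidationError(
                    f"{label}: cumulative count decreases at t_{times[i]} "
                    f"({counts[i - 1]} -> {counts[i]})"
                )


@dataclass(frozen=True)
class FieldCageRecord:
    """One sentinel cage's cumulative dead counts at 0 h, 0.5 h, and 12 h."""

    strain: str
    product: str
    distance_ft: int
    replicate_id: str
    n_introduced: int
    dead_0h: int
    dead_05h: int
    dead_12h: int
    is_control: bool = False

    def __post_init__(self) -> None:
        label = f"cage {self.strain}/{self.product}/{self.distance_ft}ft/{self.replicate_id}"
        if self.n_introduced < 0:
            raise ValidationError(f"{label}: n_introduced must be >= 0")
        if not 0 <= self.dead_0h <= self.dead_05h <= self.dead_12h <= self.n_introduced:
            raise ValidationError(
                f"{label}: dead counts must satisfy 0 <= {self.dead_0h} <= "
                f"{self.dead_05h} <= {self.dead_12h} <= n ({self.n_introduced})"
            )

    @property
    def mortality_12h_pct(self) -> float:
        """Percent mortality at the 12 h check (0-100 scale)."""
        if self.n_introduced == 0:
            raise ValidationError(
                f"cage {self.strain}/{self.product}/{self.replicate_id}: no mosquitoes introduced"
            )
        return 100.0 * self.dead_12h / self.n_introduced


@dataclass
class StudyDataset:
    """A matched bottle-bioassay and sentinel-cage study."""

    bottles: list[BottleAssay]
    cages: list[FieldCageRecord]
    schedule: ObservationSchedule = field(default_factory=ObservationSchedule.canonical)

    def bottle_groups(self) -> dict[tuple[str, ChemicalTreatment], list[BottleAssay]]:
        """Bottles grouped by strain x treatment, preserving input order."""
        groups: dict[tuple[str, ChemicalTreatment], list[BottleAssay]] = {}
        for b in self.bottles:
            groups.setdefault((b.strain, b.treatment), []).append(b)
        return groups

    def cage_groups(self) -> dict[tuple[str, str], list[FieldCageRecord]]:
        """Treated cages grouped by strain x product."""
        groups: dict[tuple[str, str], list[FieldCageRecord]] = {}
        for c in self.cages:
            if not c.is_control:
                groups.setdefault((c.strain, c.product), []).append(c)
        return groups

    def control_cages(self, strain: str) -> list[FieldCageRecord]:
        return [c for c in self.cages if c.is_control and c.strain == strain]

    def control_bottles(self, strain: str) -> list[BottleAssay]:
        return [b for b in self.bottles if b.treatment.is_control and b.strain == strain]


def group_key(records: Iterable[BottleAssay]) -> tuple[str, ChemicalTreatment]:
    """Common (strain, treatment) of a replicate collection; raises on a mixed group."""
    from .errors import GroupingError

    records = list(records)
    if not records:
        raise GroupingError("empty replicate collection")
    keys = {(b.strain, b.treatment) for b in records}
    if len(keys) > 1:
        raise GroupingError(f"mixed strain/treatment groups: {sorted(str(k) for k in keys)}")
    return keys.pop()
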