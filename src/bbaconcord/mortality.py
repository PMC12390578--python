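"""Cumulative mortality curves, Abbott's control correction, and field summaries.

Replicate aggregation is the unweighted mean of per-bottle (per-cage)
percentages rather than pooled counts: replicate displays in this assay are
mean +/- SE across bottles, and the two aggregations differ only when escapes
leave bottles with slightly unequal n. The standard error uses the n-1 sample
standard deviation and is reported as 0 for a single replicate.

Abbott's formula, 100 * (T - C) / (100 - C), removes spontaneous control
mortality C from a treatment mortality T. By the CDC convention it is applied
only when control mortality averages strictly above 3% for a strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GroupingError, UndefinedCorrectionError, ValidationError
from .types import BottleAssay, ChemicalTreatment, FieldCageRecord, group_key

#: Mean control mortality (percent) above which Abbott's correction is applied.
ABBOTT_TRIGGER_PCT = 3.0


@dataclass(frozen=True)
class MortalityCurve:
    """Replicate-averaged percent mortality over time for one strain x treatment."""

    strain: str
    treatment: ChemicalTreatment
    times: tuple[int, ...]
    mean_pct: tuple[float, ...]
    se_pct: tuple[float, ...]
    n_replicates: int
    n_total: int

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.mean_pct) == len(self.se_pct)):
            raise ValidationError("curve arrays must share one length")
        arr = np.asarray(self.mean_pct)
        if np.any(arr < -1e-9) or np.any(arr > 100 + 1e-9):
            raise ValidationError("mean mortality must lie in [0, 100]")
        if np.any(np.diff(arr) < -1e-9):
            raise ValidationError("cumulative mean mortality must be non-decreasing")

    def at(self, time_min: int) -> float:
        """Mean percent mortality at a schedule time."""
        try:
            return self.mean_pct[self.times.index(time_min)]
        except ValueError:
            raise ValidationError(f"{time_min} min is not on the curve's schedule") from None


@dataclass(frozen=True)
class FieldTrialSummary:
    """Mean 12 h sentinel-cage mortality for one strain x product."""

    strain: str
    product: str
    mean_12h_pct: float
    se_pct: float
    per_distance: dict[int, tuple[float, float, int]]  # distance -> (mean, se, n_cages)
    n_cages: int
    n_total: int
    abbott_applied: bool
    raw_mean_12h_pct: float
    control_mean_pct: float


def bottle_mortality_pct(bottle: BottleAssay) -> np.ndarray:
    """Percent-mortality series for one bottle: 100 * down / n at each time."""
    if bottle.n_introduced == 0:
        raise ValidationError(
            f"bottle {bottle.strain}/{bottle.treatment.name}/{bottle.replicate_id}: "
            "no mosquitoes introduced; mortality undefined"
        )
    return 100.0 * np.asarray(bottle.down_counts, dtype=float) / bottle.n_introduced


def pct_matrix(bottles: Sequence[BottleAssay]) -> np.ndarray:
    """Stack per-bottle percent series into an (n_bottles, n_times) array."""
    return np.vstack([bottle_mortality_pct(b) for b in bottles])


def _mean_se(values: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[axis]
    mean = values.mean(axis=axis)
    if n == 1:
        return mean, np.zeros_like(mean)
    se = values.std(axis=axis, ddof=1) / math.sqrt(n)
    return mean, se


def mean_curve(bottles: Sequence[BottleAssay]) -> MortalityCurve:
    """Average replicate bottles of one strain x treatment into a MortalityCurve."""
    bottles = list(bottles)
    strain, treatment = group_key(bottles)
    schedules = {b.schedule for b in bottles}
    if len(schedules) > 1:
        raise GroupingError("replicate bottles must share one observation schedule")
    mat = pct_matrix(bottles)
    mean, se = _mean_se(mat)
    return MortalityCurve(
        strain=strain,
        treatment=treatment,
        times=bottles[0].schedule.times,
        mean_pct=tuple(float(x) for x in mean),
        se_pct=tuple(float(x) for x in se),
        n_replicates=len(bottles),
        n_total=sum(b.n_introduced for b in bottles),
    )


def abbott_correct(test_pct: float, control_pct: float) -> float:
    """Abbott's control-mortality correction, clamped below at 0.

    Negative corrected mortality (test below control) is not interpretable and
    is reported as 0.
    """
    if not 0 <= test_pct <= 100:
        raise ValidationError(f"test mortality {test_pct} outside [0, 100]")
    if not 0 <= control_pct <= 100:
        raise ValidationError(f"control mortality {control_pct} outside [0, 100]")
    if control_pct == 100:
        raise UndefinedCorrectionError("Abbott correction undefined at 100% control mortality")
    if control_pct == 0:
        return float(test_pct)  # exact identity; x/100*100 need not round-trip in floats
    return max(0.0, 100.0 * (test_pct - control_pct) / (100.0 - control_pct))


def control_trigger(
    controls: Sequence[BottleAssay] | Sequence[FieldCageRecord],
) -> tuple[bool, float]:
    """Whether mean control mortality exceeds the 3% Abbott trigger, and its value.

    Control bottles contribute their final-time mortality; control cages their
    12 h mortality. The trigger uses a strict inequality, so exactly 3% does
    not trigger correction.
    """
    controls = list(controls)
    if not controls:
        raise ValidationError("no control units supplied")
    pcts = []
    for unit in controls:
        if isinstance(unit, BottleAssay):
            pcts.append(float(bottle_mortality_pct(unit)[-1]))
        else:
            pcts.append(unit.mortality_12h_pct)
    mean_control = float(np.mean(pcts))
    return mean_control > ABBOTT_TRIGGER_PCT, mean_control


def field_summary(
    cages: Sequence[FieldCageRecord],
    controls: Sequence[FieldCageRecord] = (),
) -> FieldTrialSummary:
    """Summarize 12 h mortality across replicate sentinel cages.

    Per-cage percentages are averaged unweighted; Abbott's correction is
    applied to the per-cage percentages only when the control cages for the
    strain average above the 3% trigger. Both raw and (possibly corrected)
    means are reported.
    """
    cages = [c for c in cages if not c.is_control]
    if not cages:
        raise GroupingError("no treated cages supplied")
    keys = {(c.strain, c.product) for c in cages}
    if len(keys) > 1:
        raise GroupingError(f"mixed strain/product cage groups: {sorted(keys)}")
    strain, product = keys.pop()

    apply_abbott, control_mean = (False, 0.0)
    if controls:
        apply_abbott, control_mean = control_trigger(list(controls))

    raw = np.array([c.mortality_12h_pct for c in cages])
    pct = (
        np.array([abbott_correct(p, control_mean) for p in raw]) if apply_abbott else raw
    )
    mean, se = _mean_se(pct)

    per_distance: dict[int, tuple[float, float, int]] = {}
    for dist in sorted({c.distance_ft for c in cages}):
        sel = pct[[i for i, c in enumerate(cages) if c.distance_ft == dist]]
        d_mean, d_se = _mean_se(sel)
        per_distance[dist] = (float(d_mean), float(d_se), len(sel))

    return FieldTrialSummary(
        strain=strain,
        product=product,
        mean_12h_pct=float(mean),
        se_pct=float(se),
        per_distance=per_distance,
        n_cages=len(cages),
        n_total=sum(c.n_introduced for c in cages),
        abbott_applied=apply_abbott,
        raw_mean_12h_pct=float(raw.mean()),
        control_mean_pct=control_mean,
    )


def curve_table(curves: Sequence[MortalityCurve]):
    """Tidy long-form table (strain, chemical, grade, time_min, mean_pct, se_pct)."""
    import pandas as pd

    rows = [
        {
            "strain": c.strain,
            "chemical": c.treatment.name,
            "grade": c.treatment.grade.value,
            "time_min": t,
            "mean_pct": m,
            "se_pct": s,
        }
        for c in curves
        for t, m, s in zip(c.times, c.mean_pct, c.se_pct)
    ]
    return pd.DataFrame(rows)


def field_table(summaries: Sequence[FieldTrialSummary]):
    """Tidy field-summary table with one overall row plus per-distance rows."""
    import pandas as pd

    rows = []
    for s in summaries:
        rows.append(
            {
                "strain": s.strain,
                "product": s.product,
                "distance_ft": "overall",
                "mean_pct": s.mean_12h_pct,
                "se_pct": s.se_pct,
                "n": s.n_cages,
                "abbott_applied": s.abbott_applied,
            }
        )
        for dist, (m, se, n) in s.per_distance.items():
            rows.append(
                {
                    "strain": s.strain,
                    "product": s.product,
                    "distance_ft": str(dist),
                    "mean_pct": m,
                    "se_pct": se,
                    "n": n,
                    "abbott_applied": s.abbott_applied,
                }
            )
    return pd.DataFrame(rows)
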