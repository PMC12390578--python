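"""Diagnostic time from a susceptible reference and CDC resistance classification.

The diagnostic time is the earliest scheduled observation at which the mean
mortality of the susceptible reference strain reaches exactly 100% — i.e.
every mosquito in every reference bottle is down. Wild-type mortality read at
that time falls into the CDC three-band classification:

* below 90%           -> resistant
* 90% to below 97%    -> developing resistance
* 97% and above       -> susceptible

The CDC wording leaves the open interval (96, 97) unassigned for continuous
percentages; this implementation extends "developing resistance" up to (but
excluding) 97, which preserves the printed 97-as-susceptible lower bound and
leaves no gap.

Formal resistance inference uses technical-grade insecticide only; reports on
formulated products are flagged, not suppressed, since formulated-product
assays are read the same way when comparing against field performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import GroupingError, NoDiagnosticTimeError, ValidationError
from .mortality import MortalityCurve
from .types import ChemicalTreatment, Grade


class Classification(str, Enum):
    RESISTANT = "resistant"
    DEVELOPING_RESISTANCE = "developing_resistance"
    SUSCEPTIBLE = "susceptible"


@dataclass(frozen=True)
class DiagnosticResult:
    """Resistance call for a wild strain against a susceptible reference."""

    strain: str
    reference_strain: str
    treatment: ChemicalTreatment
    diagnostic_time: int
    mortality_at_dt: float
    classification: Classification
    formulated_flag: bool

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "reference": self.reference_strain,
            "chemical": self.treatment.name,
            "grade": self.treatment.grade.value,
            "dose_ug": self.treatment.dose_ug,
            "diagnostic_time_min": self.diagnostic_time,
            "mortality_at_dt_pct": self.mortality_at_dt,
            "classification": self.classification.value,
            "formulated_flag": self.formulated_flag,
        }


def diagnostic_time(reference_curve: MortalityCurve) -> int:
    """Earliest schedule time at which the reference mean mortality is 100%.

    Equality is exact: per-bottle percentages are 100 only when every mosquito
    is down, and a float mean of values <= 100 equals 100 only when all are,
    so no tolerance is applied.
    """
    for t, pct in zip(reference_curve.times, reference_curve.mean_pct):
        if pct >= 100.0:
            return t
    raise NoDiagnosticTimeError(
        f"reference {reference_curve.strain}/{reference_curve.treatment.name} never "
        f"reached 100% mortality within {reference_curve.times[-1]} min; "
        "assay not interpretable"
    )


def classify(mortality_at_dt: float) -> Classification:
    """CDC three-band call from percent mortality at the diagnostic time."""
    if not 0 <= mortality_at_dt <= 100:
        raise ValidationError(f"mortality {mortality_at_dt} outside [0, 100]")
    if mortality_at_dt < 90:
        return Classification.RESISTANT
    if mortality_at_dt < 97:
        return Classification.DEVELOPING_RESISTANCE
    return Classification.SUSCEPTIBLE


def resistance_report(
    wild_curve: MortalityCurve, reference_curve: MortalityCurve
) -> DiagnosticResult:
    """Combine diagnostic time, wild-type mortality there, and the CDC call.

    The two curves must share treatment and schedule. A formulated treatment
    is flagged (``formulated_flag``) without blocking the classification.
    """
    if wild_curve.treatment != reference_curve.treatment:
        raise GroupingError(
            f"treatment mismatch: wild {wild_curve.treatment.name} vs "
            f"reference {reference_curve.treatment.name}"
        )
    if wild_curve.times != reference_curve.times:
        raise GroupingError("wild and reference curves must share one schedule")
    dt = diagnostic_time(reference_curve)
    mortality = wild_curve.at(dt)
    return DiagnosticResult(
        strain=wild_curve.strain,
        reference_strain=reference_curve.strain,
        treatment=wild_curve.treatment,
        diagnostic_time=dt,
        mortality_at_dt=mortality,
        classification=classify(mortality),
        formulated_flag=wild_curve.treatment.grade is Grade.FORMULATED,
    )
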