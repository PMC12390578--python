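import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bbaconcord import (
    BottleAssay,
    ChemicalTreatment,
    FieldCageRecord,
    Grade,
    ObservationSchedule,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DELTAMETHRIN = ChemicalTreatment("deltamethrin", Grade.TECHNICAL, 22.0)
DELTAGARD = ChemicalTreatment("Deltagard", Grade.FORMULATED, 22.0)
ACETONE = ChemicalTreatment("acetone", Grade.SOLVENT_CONTROL, 0.0)


@pytest.fixture
def schedule():
    return ObservationSchedule.canonical()


def make_bottle(
    counts,
    n=25,
    strain="Fogg Rd",
    treatment=DELTAMETHRIN,
    replicate="1",
    schedule=None,
):
    """Build a bottle from an arbitrary cumulative count sequence.

    If ``counts`` is shorter than the schedule the final value is held
    (cumulative counts plateau).
    """
    schedule = schedule or ObservationSchedule.canonical()
    counts = list(counts)
    counts += [counts[-1]] * (len(schedule) - len(counts))
    return BottleAssay(
        strain=strain,
        treatment=treatment,
        replicate_id=replicate,
        n_introduced=n,
        down_counts=tuple(counts),
        schedule=schedule,
    )


def make_cage(
    dead_12h,
    n=20,
    strain="Fogg Rd",
    product="Deltagard",
    distance=100,
    replicate="1",
    is_control=False,
    dead_05h=None,
):
    return FieldCageRecord(
        strain=strain,
        product=product,
        distance_ft=distance,
        replicate_id=replicate,
        n_introduced=n,
        dead_0h=0,
        dead_05h=dead_12h if dead_05h is None else dead_05h,
        dead_12h=dead_12h,
        is_control=is_control,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2023)
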