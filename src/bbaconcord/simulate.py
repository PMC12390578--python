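"""Synthetic bottle-bioassay and sentinel-cage study generator.

Knockdown times are drawn from a log-logistic law — median ``kt50`` (the KT50)
and shape parameter ``shape``, CDF F(t) = 1 / (1 + (t/kt50)^(-shape)) — whose
closed-form quantile makes inverse-transform sampling exact and whose heavy
right tail mimics the delayed knockdown of formulated products. A Weibull
alternative (parameterized by the same median) is available. A refractory
``immune_fraction`` never goes down within the assay, producing the flat
sub-100% plateaus seen in resistant populations; spontaneous control
mortality is an independent per-mosquito event at rate ``control_rate``.

Each simulated mosquito's knockdown time is censored onto the observation
schedule as a cumulative count: a mosquito with time <= t is down at t. All
randomness flows through one explicitly passed numpy Generator.

Preset scenarios (one per wild strain x chemistry panel) encode the study
conditions: 4 replicate bottles of ~25 females plus 4 acetone controls per
strain x chemical, and 9 treated cages of ~20 females across 100/200/300 ft
transects plus 3 controls per strain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import ValidationError
from .types import (
    STANDARD_DISTANCES,
    BottleAssay,
    ChemicalTreatment,
    FieldCageRecord,
    Grade,
    ObservationSchedule,
    StudyDataset,
)

KnockdownLaw = Literal["loglogistic", "weibull"]


@dataclass(frozen=True)
class StrainProfile:
    """Knockdown phenotype of one strain under one treatment."""

    name: str
    kt50: float
    shape: float
    immune_fraction: float = 0.0
    control_rate: float = 0.01
    law: KnockdownLaw = "loglogistic"

    def __post_init__(self) -> None:
        if self.kt50 <= 0 or self.shape <= 0:
            raise ValidationError(f"profile {self.name}: kt50 and shape must be > 0")
        if not 0 <= self.immune_fraction <= 1:
            raise ValidationError(f"profile {self.name}: immune_fraction outside [0, 1]")
        if not 0 <= self.control_rate <= 0.03:
            raise ValidationError(f"profile {self.name}: control_rate outside [0, 0.03]")
        if self.law not in ("loglogistic", "weibull"):
            raise ValidationError(f"profile {self.name}: unknown law {self.law!r}")

    def cdf(self, t: np.ndarray | float) -> np.ndarray | float:
        """Knockdown-time CDF among the non-immune subpopulation."""
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            if self.law == "loglogistic":
                out = np.where(t > 0, 1.0 / (1.0 + (t / self.kt50) ** (-self.shape)), 0.0)
            else:
                scale = self.kt50 / np.log(2.0) ** (1.0 / self.shape)
                out = np.where(t > 0, 1.0 - np.exp(-((t / scale) ** self.shape)), 0.0)
        return out if out.ndim else float(out)

    def expected_mortality_pct(self, t: np.ndarray | float) -> np.ndarray | float:
        """Expected percent down by time t, immune mass included."""
        return 100.0 * (1.0 - self.immune_fraction) * self.cdf(t)


def sample_knockdown_times(
    n: int, profile: StrainProfile, rng: np.random.Generator
) -> np.ndarray:
    """Draw n knockdown times in minutes; immune mosquitoes get +inf.

    Sampling is by inverse transform on the closed-form quantile:
    log-logistic Q(u) = kt50 * (u/(1-u))^(1/shape); Weibull Q(u) with the
    scale set so the median is kt50.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    immune = rng.random(n) < profile.immune_fraction
    u = rng.random(n)
    if profile.law == "loglogistic":
        times = profile.kt50 * (u / (1.0 - u)) ** (1.0 / profile.shape)
    else:
        scale = profile.kt50 / np.log(2.0) ** (1.0 / profile.shape)
        times = scale * (-np.log(1.0 - u)) ** (1.0 / profile.shape)
    times[immune] = np.inf
    return times


def censor_to_schedule(times: np.ndarray, schedule: ObservationSchedule) -> tuple[int, ...]:
    """Cumulative down-counts on the schedule: #(knockdown time <= t) per t."""
    grid = np.asarray(schedule.times, dtype=float)
    return tuple(int(np.sum(times <= t)) for t in grid)


def simulate_bottle(
    profile: StrainProfile,
    treatment: ChemicalTreatment,
    rng: np.random.Generator,
    schedule: ObservationSchedule | None = None,
    n_per_bottle: int = 25,
    replicate_id: str = "1",
    strain: str | None = None,
    escape_prob: float = 0.15,
) -> BottleAssay:
    """Simulate one bottle; with probability ``escape_prob`` one female escapes."""
    schedule = schedule or ObservationSchedule.canonical()
    n = n_per_bottle - int(rng.random() < escape_prob)
    times = sample_knockdown_times(n, profile, rng)
    return BottleAssay(
        strain=strain or profile.name,
        treatment=treatment,
        replicate_id=replicate_id,
        n_introduced=n,
        down_counts=censor_to_schedule(times, schedule),
        schedule=schedule,
    )


def simulate_control_bottle(
    strain: str,
    control_rate: float,
    rng: np.random.Generator,
    schedule: ObservationSchedule | None = None,
    n_per_bottle: int = 25,
    replicate_id: str = "1",
    escape_prob: float = 0.15,
) -> BottleAssay:
    """Acetone-only bottle: spontaneous knockdown at uniform times, rate <= 3%."""
    schedule = schedule or ObservationSchedule.canonical()
    n = n_per_bottle - int(rng.random() < escape_prob)
    down = rng.random(n) < control_rate
    times = np.full(n, np.inf)
    times[down] = rng.uniform(0.0, schedule.times[-1], size=int(down.sum()))
    return BottleAssay(
        strain=strain,
        treatment=ChemicalTreatment("acetone", Grade.SOLVENT_CONTROL, 0.0),
        replicate_id=replicate_id,
        n_introduced=n,
        down_counts=censor_to_schedule(times, schedule),
        schedule=schedule,
    )


@dataclass(frozen=True)
class ArmSpec:
    """One bioassay arm: a treatment and the knockdown profiles per strain."""

    treatment: ChemicalTreatment
    profiles: dict[str, StrainProfile]  # strain -> profile under this treatment


@dataclass(frozen=True)
class ScenarioConfig:
    """Full study layout: bioassay arms, field efficacies, and design counts."""

    name: str
    wild_strain: str
    reference_strain: str
    arms: tuple[ArmSpec, ...]
    field_efficacy: dict[str, dict[str, float]]  # product -> strain -> P(dead by 12 h)
    n_bottles: int = 4
    n_per_bottle: int = 25
    escape_prob: float = 0.15
    cages_per_distance: int = 3
    n_per_cage: int = 20
    early_death_fraction: float = 0.5
    control_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for v, what in (
            (self.n_bottles, "n_bottles"),
            (self.n_per_bottle, "n_per_bottle"),
            (self.cages_per_distance, "cages_per_distance"),
            (self.n_per_cage, "n_per_cage"),
        ):
            if v < 1:
                raise ValidationError(f"{what} must be >= 1")
        for p, what in (
            (self.escape_prob, "escape_prob"),
            (self.early_death_fraction, "early_death_fraction"),
        ):
            if not 0 <= p <= 1:
                raise ValidationError(f"{what} outside [0, 1]")
        for product, by_strain in self.field_efficacy.items():
            for strain, eff in by_strain.items():
                if not 0 <= eff <= 1:
                    raise ValidationError(
                        f"field efficacy for {strain}/{product} outside [0, 1]"
                    )


def simulate_bottle_assays(
    cfg: ScenarioConfig, rng: np.random.Generator, schedule: ObservationSchedule | None = None
) -> list[BottleAssay]:
    """All treated bottles plus per-strain acetone controls for a scenario."""
    schedule = schedule or ObservationSchedule.canonical()
    bottles: list[BottleAssay] = []
    strains = sorted({s for arm in cfg.arms for s in arm.profiles})
    for arm in cfg.arms:
        for strain in sorted(arm.profiles):
            for rep in range(cfg.n_bottles):
                bottles.append(
                    simulate_bottle(
                        arm.profiles[strain],
                        arm.treatment,
                        rng,
                        schedule=schedule,
                        n_per_bottle=cfg.n_per_bottle,
                        replicate_id=str(rep + 1),
                        strain=strain,
                        escape_prob=cfg.escape_prob,
                    )
                )
    for strain in strains:
        for rep in range(cfg.n_bottles):
            bottles.append(
                simulate_control_bottle(
                    strain,
                    cfg.control_rate,
                    rng,
                    schedule=schedule,
                    n_per_bottle=cfg.n_per_bottle,
                    replicate_id=str(rep + 1),
                    escape_prob=cfg.escape_prob,
                )
            )
    return bottles


def simulate_field_trial(cfg: ScenarioConfig, rng: np.random.Generator) -> list[FieldCageRecord]:
    """Sentinel cages: binomial 12 h mortality per cage plus control cages.

    For each strain x product, ``cages_per_distance`` cages are deployed at
    each standard transect distance; dead_12h ~ Binomial(n, efficacy), with the
    0.5 h count a binomial thinning of the 12 h count (``early_death_fraction``)
    and the pre-deployment count 0 by construction.
    """
    cages: list[FieldCageRecord] = []
    strains: set[str] = set()
    for product in sorted(cfg.field_efficacy):
        for strain in sorted(cfg.field_efficacy[product]):
            strains.add(strain)
            eff = cfg.field_efficacy[product][strain]
            rep = 0
            for dist in STANDARD_DISTANCES:
                for _ in range(cfg.cages_per_distance):
                    rep += 1
                    n = cfg.n_per_cage
                    dead_12h = int(rng.binomial(n, eff))
                    dead_05h = int(rng.binomial(dead_12h, cfg.early_death_fraction))
                    cages.append(
                        FieldCageRecord(
                            strain=strain,
                            product=product,
                            distance_ft=dist,
                            replicate_id=str(rep),
                            n_introduced=n,
                            dead_0h=0,
                            dead_05h=dead_05h,
                            dead_12h=dead_12h,
                            is_control=False,
                        )
                    )
    for strain in sorted(strains):
        for i, dist in enumerate(STANDARD_DISTANCES):
            n = cfg.n_per_cage
            dead_12h = int(rng.binomial(n, cfg.control_rate))
            dead_05h = int(rng.binomial(dead_12h, cfg.early_death_fraction))
            cages.append(
                FieldCageRecord(
                    strain=strain,
                    product="control",
                    distance_ft=dist,
                    replicate_id=f"C{i + 1}",
                    n_introduced=n,
                    dead_0h=0,
                    dead_05h=dead_05h,
                    dead_12h=dead_12h,
                    is_control=True,
                )
            )
    return cages


def simulate_study(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> StudyDataset:
    """Generate the complete matched bioassay + field-trial dataset."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    schedule = ObservationSchedule.canonical()
    return StudyDataset(
        bottles=simulate_bottle_assays(cfg, rng, schedule),
        cages=simulate_field_trial(cfg, rng),
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# Preset scenarios
# ---------------------------------------------------------------------------
# One preset per wild strain x chemistry panel of the study design: deltamethrin
# chemistry (technical deltamethrin at 22 ug/bottle vs formulated Deltagard) and
# malathion chemistry (technical malathion at 400 ug/bottle vs Fyfanon EW), each
# against a fully susceptible reference (CQ1 for Cx. pipiens, KNWR for Cx.
# tarsalis) and a wild population (Fogg Rd, Vic Fazio). The kt50/shape/immune
# parameters are fixed so the expected curves show the study's qualitative
# pattern: the susceptible reference completes by its diagnostic time, the
# formulated deltamethrin arm completes by 120 min, technical deltamethrin
# plateaus below 90%, and the resistant malathion-chemistry arms plateau near
# 55% at 180 min.

PRESET_NAMES = (
    "fogg_deltamethrin",
    "fogg_malathion",
    "vicfazio_deltamethrin",
    "vicfazio_malathion",
)

_DELTAMETHRIN = ChemicalTreatment("deltamethrin", Grade.TECHNICAL, 22.0)
_DELTAGARD = ChemicalTreatment("Deltagard", Grade.FORMULATED, 22.0)
_MALATHION = ChemicalTreatment("malathion", Grade.TECHNICAL, 400.0)
_FYFANON = ChemicalTreatment("Fyfanon EW", Grade.FORMULATED, 400.0)


def _preset_table() -> dict[str, ScenarioConfig]:
    p = StrainProfile
    return {
        "fogg_deltamethrin": ScenarioConfig(
            name="fogg_deltamethrin",
            wild_strain="Fogg Rd",
            reference_strain="CQ1",
            arms=(
                ArmSpec(
                    _DELTAMETHRIN,
                    {
                        "CQ1": p("CQ1", kt50=8.0, shape=7.0),
                        "Fogg Rd": p("Fogg Rd", kt50=62.0, shape=2.0, immune_fraction=0.10),
                    },
                ),
                ArmSpec(
                    _DELTAGARD,
                    {
                        "CQ1": p("CQ1", kt50=4.5, shape=8.0),
                        "Fogg Rd": p("Fogg Rd", kt50=14.0, shape=5.0),
                    },
                ),
            ),
            field_efficacy={"Deltagard": {"CQ1": 1.0, "Fogg Rd": 0.977}},
        ),
        "fogg_malathion": ScenarioConfig(
            name="fogg_malathion",
            wild_strain="Fogg Rd",
            reference_strain="CQ1",
            arms=(
                ArmSpec(
                    _MALATHION,
                    {
                        "CQ1": p("CQ1", kt50=14.0, shape=7.0),
                        "Fogg Rd": p("Fogg Rd", kt50=18.0, shape=5.5),
                    },
                ),
                ArmSpec(
                    _FYFANON,
                    {
                        "CQ1": p("CQ1", kt50=9.0, shape=7.0),
                        "Fogg Rd": p("Fogg Rd", kt50=20.0, shape=4.0),
                    },
                ),
            ),
            field_efficacy={"Fyfanon EW": {"CQ1": 1.0, "Fogg Rd": 1.0}},
        ),
        "vicfazio_deltamethrin": ScenarioConfig(
            name="vicfazio_deltamethrin",
            wild_strain="Vic Fazio",
            reference_strain="KNWR",
            arms=(
                ArmSpec(
                    _DELTAMETHRIN,
                    {
                        "KNWR": p("KNWR", kt50=18.0, shape=7.0),
                        "Vic Fazio": p("Vic Fazio", kt50=95.0, shape=2.2, immune_fraction=0.12),
                    },
                ),
                ArmSpec(
                    _DELTAGARD,
                    {
                        "KNWR": p("KNWR", kt50=4.5, shape=8.0),
                        "Vic Fazio": p("Vic Fazio", kt50=26.0, shape=4.5),
                    },
                ),
            ),
            field_efficacy={"Deltagard": {"KNWR": 1.0, "Vic Fazio": 0.994}},
        ),
        "vicfazio_malathion": ScenarioConfig(
            name="vicfazio_malathion",
            wild_strain="Vic Fazio",
            reference_strain="KNWR",
            arms=(
                ArmSpec(
                    _MALATHION,
                    {
                        "KNWR": p("KNWR", kt50=20.0, shape=7.0),
                        "Vic Fazio": p("Vic Fazio", kt50=82.0, shape=2.8, immune_fraction=0.40),
                    },
                ),
                ArmSpec(
                    _FYFANON,
                    {
                        "KNWR": p("KNWR", kt50=25.0, shape=7.0),
                        "Vic Fazio": p("Vic Fazio", kt50=95.0, shape=2.8, immune_fraction=0.36),
                    },
                ),
            ),
            field_efficacy={"Fyfanon EW": {"KNWR": 1.0, "Vic Fazio": 0.474}},
        ),
    }


def preset_scenario(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """A named study-design preset; ``overrides`` replace config fields."""
    presets = _preset_table()
    if name not in presets:
        raise ValidationError(f"unknown scenario {name!r}; choose from {PRESET_NAMES}")
    return replace(presets[name], seed=seed, **overrides)
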