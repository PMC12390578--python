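"""Study-level orchestration: curves, field summaries, resistance calls,
and concordance comparisons for a matched bioassay + field-trial dataset.

This layer is what the command-line interface (and the example scripts) drive.
A :class:`RunConfig` captures everything a run needs — the wild-to-reference
strain mapping, the technical/formulated product pairing per chemistry, and
the bootstrap settings — so a run is reproducible from one serializable
object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

from .concordance import ConcordanceResult, bootstrap_rmse_diff
from .errors import ValidationError
from .mortality import MortalityCurve, FieldTrialSummary, control_trigger, field_summary, mean_curve
from .resistance import DiagnosticResult, resistance_report
from .types import StudyDataset

logger = logging.getLogger("bbaconcord")


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    reference_map: dict[str, str]  # wild strain -> susceptible reference strain
    pairings: dict[str, str] = dc_field(default_factory=dict)  # formulated product -> technical standard
    n_boot: int = 1000
    seed: int = 0
    ci_method: str = "percentile"
    resample_unit: str = "replicates"
    include_t0: bool = True

    def __post_init__(self) -> None:
        refs = list(self.reference_map.values())
        if len(set(self.reference_map)) != len(self.reference_map):
            raise ValidationError("duplicate wild strains in reference map")
        for wild, ref in self.reference_map.items():
            if wild == ref:
                raise ValidationError(f"strain {wild} cannot be its own reference")


@dataclass
class AnalysisResult:
    """Everything the analyze stage computes."""

    curves: list[MortalityCurve]
    field_summaries: list[FieldTrialSummary]
    diagnostics: list[DiagnosticResult]
    abbott_log: dict[str, dict]


def analyze_study(ds: StudyDataset, config: RunConfig) -> AnalysisResult:
    """Mean curves per strain x treatment, field summaries, and resistance calls.

    The Abbott >3% trigger is evaluated per strain for bottles (acetone
    controls at the final time) and for cages (control cages at 12 h), and the
    decision is logged and returned.
    """
    curves: dict[tuple[str, str], MortalityCurve] = {}
    for (strain, treatment), bottles in ds.bottle_groups().items():
        if treatment.is_control:
            continue
        curves[(strain, treatment.name)] = mean_curve(bottles)

    abbott_log: dict[str, dict] = {}
    strains = sorted({b.strain for b in ds.bottles} | {c.strain for c in ds.cages})
    for strain in strains:
        entry: dict = {}
        bottle_controls = ds.control_bottles(strain)
        if bottle_controls:
            trig, mean_c = control_trigger(bottle_controls)
            entry["bottles"] = {"trigger": trig, "mean_control_pct": mean_c}
            logger.info(
                "strain %s: acetone-control mortality %.2f%% -> Abbott %s (bottles)",
                strain, mean_c, "APPLIED" if trig else "not applied",
            )
        cage_controls = ds.control_cages(strain)
        if cage_controls:
            trig, mean_c = control_trigger(cage_controls)
            entry["cages"] = {"trigger": trig, "mean_control_pct": mean_c}
            logger.info(
                "strain %s: control-cage mortality %.2f%% -> Abbott %s (cages)",
                strain, mean_c, "APPLIED" if trig else "not applied",
            )
        abbott_log[strain] = entry

    summaries = [
        field_summary(cages, ds.control_cages(strain))
        for (strain, _product), cages in sorted(ds.cage_groups().items())
    ]

    diagnostics = []
    for (strain, chem), wild_curve in sorted(curves.items()):
        ref_strain = config.reference_map.get(strain)
        if ref_strain is None:
            continue
        ref_curve = curves.get((ref_strain, chem))
        if ref_curve is None:
            raise ValidationError(
                f"reference strain {ref_strain} has no {chem} bioassay to compare "
                f"against wild strain {strain}"
            )
        result = resistance_report(wild_curve, ref_curve)
        logger.info(
            "strain %s vs %s (%s): diagnostic time %d min, mortality %.1f%% -> %s",
            strain, ref_strain, chem, result.diagnostic_time,
            result.mortality_at_dt, result.classification.value,
        )
        diagnostics.append(result)

    return AnalysisResult(
        curves=list(curves.values()),
        field_summaries=summaries,
        diagnostics=diagnostics,
        abbott_log=abbott_log,
    )


def concordance_set(ds: StudyDataset, config: RunConfig) -> list[ConcordanceResult]:
    """One technical-vs-formulated comparison per wild strain x chemistry.

    For each formulated product paired with a technical standard, and each
    wild strain with treated cages under that product, the bioassay arms are
    the wild strain's bottles under the technical (arm a) and formulated
    (arm b) treatments, and field performance is the 12 h mortality of the
    strain's cages under the formulated product.
    """
    groups = ds.bottle_groups()
    by_strain_chem = {
        (strain, t.name): bottles for (strain, t), bottles in groups.items() if not t.is_control
    }
    results = []
    for (strain, product), cages in sorted(ds.cage_groups().items()):
        technical = config.pairings.get(product)
        if technical is None or strain not in config.reference_map:
            continue
        bottles_a = by_strain_chem.get((strain, technical))
        bottles_b = by_strain_chem.get((strain, product))
        if bottles_a is None or bottles_b is None:
            raise ValidationError(
                f"strain {strain}: pairing {technical} <-> {product} needs bioassay "
                "arms for both treatments"
            )
        result = bootstrap_rmse_diff(
            bottles_a,
            bottles_b,
            cages,
            n_boot=config.n_boot,
            seed=config.seed,
            ci_method=config.ci_method,
            resample_unit=config.resample_unit,
            include_t0=config.include_t0,
        )
        logger.info(
            "strain %s %s: RMSE %s=%.2f %s=%.2f, boot mean diff %.2f (95%% CI %.2f, %.2f)%s",
            strain, result.diff_label, technical, result.rmse_a, product, result.rmse_b,
            result.boot_mean_diff, result.ci_low, result.ci_high,
            " *" if result.significant else "",
        )
        results.append(result)
    return results
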