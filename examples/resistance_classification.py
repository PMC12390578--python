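"""Classify insecticide resistance from bottle-bioassay time-mortality curves.

Simulates the Vic Fazio / malathion-chemistry panel, finds the diagnostic
time (earliest observation at which the susceptible KNWR reference reaches
100% mortality), reads wild-type mortality there, and applies the CDC bands:
<90% resistant, 90-<97% developing resistance, >=97% susceptible.
"""

from bbaconcord import (
    RunConfig,
    analyze_study,
    preset_scenario,
    simulate_study,
)

cfg = preset_scenario("vicfazio_malathion", seed=7)
ds = simulate_study(cfg)
analysis = analyze_study(ds, RunConfig(reference_map={"Vic Fazio": "KNWR"}))

for d in analysis.diagnostics:
    flag = " (formulated product: flagged, not used for formal inference)" if d.formulated_flag else ""
    print(
        f"{d.strain} vs {d.reference_strain}, {d.treatment.name}: "
        f"diagnostic time {d.diagnostic_time} min, "
        f"mortality {d.mortality_at_dt:.1f}% -> {d.classification.value}{flag}"
    )
# Low wild-type mortality at the diagnostic time indicates a resistant
# population even when mortality keeps rising later in the assay.
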