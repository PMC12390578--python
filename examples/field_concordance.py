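"""Score how well each bioassay arm predicts field performance.

Simulates the Fogg Rd / deltamethrin-chemistry panel and compares the
technical-grade and formulated (Deltagard) bioassay curves against mean 12 h
sentinel-cage mortality via RMSE, then bootstraps the RMSE difference
(technical - formulated) over replicate bottles and cages: a 95% interval
excluding zero means one arm tracks the field result significantly better.
"""

from bbaconcord import RunConfig, concordance_set, preset_scenario, simulate_study

cfg = preset_scenario("fogg_deltamethrin", seed=42)
ds = simulate_study(cfg)
run_cfg = RunConfig(
    reference_map={"Fogg Rd": "CQ1"},
    pairings={"Deltagard": "deltamethrin"},
    n_boot=1000,
    seed=42,
)

for r in concordance_set(ds, run_cfg):
    print(f"strain {r.strain}, field 12 h mortality {r.field_mean_pct:.1f}%")
    print(f"  RMSE {r.label_a} (technical):  {r.rmse_a:.2f} percentage points")
    print(f"  RMSE {r.label_b} (formulated): {r.rmse_b:.2f} percentage points")
    print(
        f"  bootstrap mean diff {r.boot_mean_diff:.2f} "
        f"(95% CI {r.ci_low:.2f}, {r.ci_high:.2f}) "
        f"-> {'significant' if r.significant else 'not significant'}"
    )
    print(
        f"  closest bioassay match to field: {r.label_a} at {r.closest_time_a} min "
        f"({r.closest_mortality_a:.1f}%), {r.label_b} at {r.closest_time_b} min "
        f"({r.closest_mortality_b:.1f}%)"
    )
# A lower RMSE for the formulated arm, with a CI excluding zero, indicates the
# formulated-product bioassay better reflects field efficacy.
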