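"""Generate a synthetic matched bioassay + sentinel-cage study and save it.

Writes bottles.csv and cages.csv (the package's CSV schemas) for the
Fogg Rd / deltamethrin-chemistry panel: 4 replicate bottles of ~25 females
per strain x chemical plus 4 acetone controls, and 9 treated cages of 20
females per strain across the 100/200/300 ft transects plus 3 controls.
"""

from pathlib import Path

from bbaconcord import preset_scenario, simulate_study, validate_dataset
from bbaconcord.io import write_bottle_assays, write_field_cages

out = Path("example_output")
out.mkdir(exist_ok=True)

cfg = preset_scenario("fogg_deltamethrin", seed=42)
ds = simulate_study(cfg)
write_bottle_assays(ds.bottles, out / "bottles.csv")
write_field_cages(ds.cages, out / "cages.csv")

report = validate_dataset(ds)
print(f"scenario: {cfg.name} (wild {cfg.wild_strain} vs reference {cfg.reference_strain})")
print(f"bottles: {len(ds.bottles)} (incl. acetone controls), cages: {len(ds.cages)}")
print(f"validation: {report}")
# A clean report means every bottle has monotone counts within [0, n] and every
# treated group has its matching solvent-control group.
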