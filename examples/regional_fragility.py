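"""End-to-end batch run: synthetic panel -> curves -> fragility and worst case.

Generates an annual country panel for one region (8 countries x 42 years,
3% missing cells) with tail dependence between yield losses and high
precipitation, runs the full pipeline for two hazards, and prints the
fragility table and worst-case index.
"""

from pathlib import Path

import croptail as ct

out = Path("scratch_example_out")
spec = ct.SyntheticSpec(family="gaussian", rho=0.6, n_countries=8, n_years=42,
                        missing_rate=0.03, seed=21)
panel, truth = ct.gen_region_fixture(spec, region="Eastern Africa")
out.mkdir(exist_ok=True)
panel.to_csv(out / "panel.csv", index=False)

cfg = ct.RunConfig(panel_csv=str(out / "panel.csv"), output_dir=str(out),
                   crops=("maize",),
                   hazards=(("prec", "high"), ("tmax", "high")),
                   grid=(0.95, 0.98), n_sim=1000, n_boot=100, seed=11)
manifest = ct.run_pipeline(cfg)

import pandas as pd

frag = pd.read_csv(out / "fragility.csv")
wc = pd.read_csv(out / "worst_case.csv")
print(f"fits attempted: {manifest['n_attempted']}, failed: {manifest['n_failed']}")
print("\nfragility table (q_c = 0.98):")
print(frag.to_string(index=False))
print("\nworst case per region:")
print(wc.to_string(index=False))
print()
print("The generated association runs through precipitation only, so the prec")
print("hazard should carry the larger, interval-supported probability while the")
print("temperature hazard's interval typically reaches zero (shown = False).")
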