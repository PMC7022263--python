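#!/usr/bin/env python
"""Baseline liposomal delivery with burst sonication: compartment timelines.

Runs the baseline scenario (50 mg/m² liposomal doxorubicin, burst
sonication at injection) for 2 h on the full voxel model at 2 mm and for
24 h on the lumped reduction, and writes the plasma/tissue concentration
timelines. The 2 h spatial run is also compared against the identical run
without sonication to quantify the barrier-disruption enhancement.

Writes results/baseline_timeline_24h.csv, results/baseline_2h_pde.csv and
results/bbbd_enhancement_2h.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from braintx.bbbd import SonicationProtocol
from braintx.flow import solve_interstitial_flow
from braintx.phantom import PhantomSpec, build_phantom
from braintx.scenarios import ModelBundle, Scenario, run_scenario

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

phantom = build_phantom(PhantomSpec.default(voxel_spacing=2e-3))
bundle = ModelBundle()
flow = solve_interstitial_flow(phantom, bundle.hydraulics)

# 24 h compartment timelines (lumped reduction; 10 min output sampling)
rep24 = run_scenario(Scenario(mode="liposome_bbbd", output_interval_s=600.0),
                     phantom, bundle, flow, method="lumped")
rep24.result.to_dataframe().to_csv(OUT / "baseline_timeline_24h.csv",
                                   index=False)
print(f"24 h exposure (lumped): AUC_IVS = {rep24.auc_ivs:.3e}, "
      f"AUC_tumour_ECS = {rep24.auc_tumour_ecs:.3e} mg/mL*s")

# 2 h spatial runs, with and without sonication
conc = {}
for mode in ("liposome_bbbd", "liposome"):
    sc = Scenario(mode=mode, t_end_s=7200.0,
                  protocol=SonicationProtocol.burst_at(0.0))
    rep = run_scenario(sc, phantom, bundle, flow, method="pde")
    conc[mode] = rep
    if mode == "liposome_bbbd":
        rep.result.to_dataframe().to_csv(OUT / "baseline_2h_pde.csv",
                                         index=False)

a = conc["liposome_bbbd"].result.c_f_ecs_tumour[-1]
b = conc["liposome"].result.c_f_ecs_tumour[-1]
pd.DataFrame([{"C_F_ECS_tumour_bbbd": a, "C_F_ECS_tumour_no_bbbd": b,
               "enhancement_ratio": a / b}]).to_csv(
    OUT / "bbbd_enhancement_2h.csv", index=False)
print(f"2 h tumour-ECS free doxorubicin: {a:.3e} (sonicated) vs {b:.3e} "
      f"(intact barrier) mg/mL -> enhancement {a / b:.2f}-fold")
print("Burst sonication leaves the wall permeable to the small free drug "
      "for hours (slow recovery), while the liposome enhancement decays in "
      "seconds; the free-drug influx drives the early tumour exposure gain.")
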