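#!/usr/bin/env python
"""Compare delivery strategies by 24 h drug exposure.

Runs the three strategies (direct free-drug bolus with sonication,
liposomes alone, liposomes with burst sonication) for 24 h on the spatial
model at 4 mm / 60 s and reports free-drug AUC in plasma, tumour ECS and
normal-tissue ECS.

Writes results/delivery_modes_auc.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from braintx.flow import solve_interstitial_flow
from braintx.phantom import PhantomSpec, build_phantom
from braintx.scenarios import ModelBundle, Scenario, run_scenario

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

phantom = build_phantom(PhantomSpec.default(voxel_spacing=4e-3))
bundle = ModelBundle()
flow = solve_interstitial_flow(phantom, bundle.hydraulics)

rows = []
for mode in ("direct_bbbd", "liposome", "liposome_bbbd"):
    rep = run_scenario(Scenario(mode=mode, dt_s=60.0), phantom, bundle, flow,
                       method="pde")
    rows.append(rep.row())
df = pd.DataFrame(rows)
df.to_csv(OUT / "delivery_modes_auc.csv", index=False)
print(df[["mode", "AUC_IVS", "AUC_tumour_ECS", "AUC_normal_ECS"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))

print("\nDirect injection wastes the dose to fast plasma clearance: its "
      "tumour exposure is an order of magnitude below either liposomal "
      "strategy. In this implementation the intact-barrier liposome arm "
      "accumulates the most free drug over 24 h, because the sonication-"
      "opened wall also lets tissue drug drain back once plasma levels "
      "fall below the release-fed tissue level; the sonicated arm leads "
      "only over the first hours (see 03).")
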