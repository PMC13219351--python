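"""Multimodal plant-moisture-content regression on the synthetic campaign.

Assembles the full observation table (vegetation indices + thermal indices
+ cumulative ET), adds 3% measurement noise to the PMC "field samples" and
compares random-forest accuracy across feature combinations with seeded
5-fold cross-validation.
"""

import numpy as np

from cropwater.pipeline import assemble_observations
from cropwater.regression import assemble_features, train_eval
from cropwater.synthetic import STAGES, generate_field_layout, generate_truth, render_scene

layout = generate_field_layout(30, seed=6)
truth = generate_truth(layout, seed=6)
scenes = {s: render_scene(truth, layout, s, seed=6) for s in STAGES}
obs = assemble_observations(layout, truth, scenes)

rng = np.random.default_rng(6)
obs["pmc"] = obs["pmc"] * (1.0 + 0.03 * rng.standard_normal(len(obs)))

stage = "grain_filling"
sub = obs[obs["stage"] == stage].reset_index(drop=True)
print(f"{stage}: {len(sub)} plots, RFR with 5-fold CV")
for combo in ("VIs", "ET", "VIs+ET", "VIs+TIs", "VIs+TIs+ET"):
    res = train_eval(assemble_features(sub, combo), sub["pmc"], "RFR",
                     search_budget=0, seed=6)
    print(f"  {combo:<11} R2 {res.r2:5.3f}   RMSE {res.rmse:.4f}   nRMSE {res.nrmse_pct:5.2f}%")
print(
    "\nThe multimodal combination performs on par with the spectral block\n"
    "here; ET alone carries little plot-level signal on this scene."
)
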