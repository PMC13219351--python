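"""Crop height from a 3-D point cloud with the AIH percentile method.

Fits a ground plane to the bare-soil survey returns, normalizes the plot's
points and reads the 90th/95th/99th accumulated-height-histogram
percentiles; the 95th is the default height estimate.
"""

import numpy as np

from cropwater.structure import aih_height, fit_ground_plane, normalize_cloud
from cropwater.synthetic import generate_field_layout, generate_truth, render_scene

layout = generate_field_layout(5, seed=4)
truth = generate_truth(layout, seed=4)
scene = render_scene(truth, layout, "heading", seed=4)

plane = fit_ground_plane(scene.ground_points)
cloud = scene.point_cloud
true_h = truth.stage_table("heading").set_index("plot_id")["height_m"]

errors = []
for rec in layout.plots.head(5).itertuples(index=False):
    sel = (
        (cloud[:, 0] >= rec.x0) & (cloud[:, 0] <= rec.x1)
        & (cloud[:, 1] >= rec.y0) & (cloud[:, 1] <= rec.y1)
    )
    z = normalize_cloud(cloud[sel], plane)
    h90, h95, h99 = (aih_height(z, p) for p in (90, 95, 99))
    print(
        f"{rec.plot_id}: AIH90 {h90:.3f}  AIH95 {h95:.3f}  AIH99 {h99:.3f}"
        f"  true {true_h[rec.plot_id]:.3f} m"
    )
    errors.append(h95 - true_h[rec.plot_id])
print(f"\nAIH95 error on these plots: {100 * np.sqrt(np.mean(np.square(errors))):.2f} cm")
print("AIH95 tracks the dominant canopy top; AIH99 reads extreme tips.")
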