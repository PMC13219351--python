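"""WUE-PMC quadratic fitting and stage irrigation thresholds.

Fits WUE = a PMC^2 + b PMC + c to (moisture, efficiency) samples; for a
concave fit, the vertex -b/(2a) is the PMC that maximizes water use
efficiency and becomes the irrigation trigger for that stage.
"""

import numpy as np
import pandas as pd

from cropwater.wue import fit_wue_pmc, optimal_pmc_threshold, prescribe

# concave WUE response peaking near 82% PMC, with sampling noise
rng = np.random.default_rng(7)
pmc_pct = rng.uniform(65, 95, 40)
wue = -0.07 * (pmc_pct - 82.0) ** 2 / 10 + 2.6 + rng.normal(0, 0.05, 40)

fit = fit_wue_pmc(zip(pmc_pct, wue), "quadratic", treatment="W3", stage="jointing")
thr = optimal_pmc_threshold(fit, (float(pmc_pct.min()), float(pmc_pct.max())))
a, b, c = fit.coefficients
print(f"quadratic fit: WUE = {a:.4f} x^2 + {b:.4f} x + {c:.4f}   (R2 {fit.r2:.3f})")
print(f"WUE-optimal PMC threshold: {thr}%")

predicted = pd.DataFrame(
    {"plot_id": ["P1", "P2", "P3"], "stage": "jointing", "pmc_pct": [70.0, thr, 90.0]}
)
print("\nprescription against that threshold:")
print(prescribe({"jointing": thr}, predicted).to_string(index=False))
print("\nPlots whose predicted moisture falls below the threshold irrigate;")
print("the rest hold, keeping the stand near its efficiency optimum.")
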