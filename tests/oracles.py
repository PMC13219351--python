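"""Independent reference implementations used to cross-check the package.

These are deliberately naive, straight-line transcriptions (written against
the published formulas, not against the package source) so that agreement
with the library is a genuine dual-route check.
"""

import math


def et_chain_oracle(
    T, u2, RH_min, Rn, G, es, ea, Delta, gamma,
    Kcb_tab, h, h_max, LAI, k, Kc_min, CWSI,
    De, REW, TEW, fw,
):
    """One day of the dual-Kc chain, transcribed term by term.

    Returns (ET0, Kcb_adjust, Kcb_a, Ks, Kc_max, fc, few, Kr, Ke, ETc, De_next).
    """
    # reference evapotranspiration
    et0 = (0.408 * Delta * (Rn - G) + gamma * (900.0 / (T + 273.0)) * u2 * (es - ea)) / (
        Delta + gamma * (1.0 + 0.34 * u2)
    )
    if et0 < 0.0:
        et0 = 0.0
    # climate adjustment of the tabulated basal coefficient
    if Kcb_tab < 0.45:
        kcb_adj = Kcb_tab
    else:
        kcb_adj = Kcb_tab + (h / 3.0) ** 0.3 * (0.04 * (u2 - 2.0) - 0.004 * (RH_min - 45.0))
    # canopy-density scaling
    kcb_a = Kc_min + (kcb_adj - Kc_min) * (1.0 - math.exp(-k * LAI))
    # stress factor from the thermal index, applied once
    ks = 1.0 - CWSI
    kcb = ks * kcb_a
    # ceiling coefficient
    kcmax = max(
        Kcb_tab + (0.04 * (u2 - 2.0) - 0.004 * (RH_min - 45.0)) * (h_max / 3.0) ** 0.3,
        kcb + 0.05,
    )
    # canopy cover fraction
    base = (kcb - Kc_min) / (kcmax - Kc_min)
    if base < 0.0:
        base = 0.0
    if base > 1.0:
        base = 1.0
    fc = base ** (1.0 + 0.5 * h)
    if fc > 0.99:
        fc = 0.99
    # exposed-and-wetted fraction
    few = min(1.0 - fc, fw)
    # two-stage evaporation reduction
    if De <= REW:
        kr = 1.0
    else:
        kr = max((TEW - De) / (TEW - REW), 0.0)
    # soil evaporation coefficient with its cap
    ke = min(kr * (kcmax - kcb), few * kcmax)
    if ke < 0.0:
        ke = 0.0
    etc = (kcb + ke) * et0
    if etc < 0.0:
        etc = 0.0
    de_next = min(De + ke * et0, TEW)
    return et0, kcb_adj, kcb_a, ks, kcmax, fc, few, kr, ke, etc, de_next


def percentile_oracle(values, p):
    """Linear-interpolation percentile by explicit sort and indexing."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    pos = (n - 1) * p / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return xs[lo] * (1.0 - frac) + xs[hi] * frac


def metrics_oracle(observed, predicted):
    """Textbook R^2 / RMSE / nRMSE via explicit summation loops."""
    n = len(observed)
    xbar = sum(observed) / n
    ss_res = sum((x - y) ** 2 for x, y in zip(observed, predicted))
    ss_tot = sum((x - xbar) ** 2 for x in observed)
    r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / n)
    nrmse = rmse / xbar * 100.0
    return r2, rmse, nrmse


def pearson_oracle(xs, ys):
    """|Pearson r| by the covariance formula."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return abs(cov / math.sqrt(vx * vy))
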