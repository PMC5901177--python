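"""Exercise the two-of-four curve exclusion screen on degenerate curves.

The generator can inject four deliberately pathological curves, one per
quality criterion: a CO2 ramp truncated at 600 ppm (max Ci < 700), a
curve still rising at the highest Ci (no plateau), a curve with large
scatter (RMSE > 6), and a low-CO2-only curve that forces the bilinear
fallback. A curve is excluded when at least two criteria are met.
"""

import tundraphys as tp
from tundraphys.synth import _qc_fixture_curves

truth = tp.default_truth(seed=42)
for curve in _qc_fixture_curves(truth, "TL", tp.KineticParams()):
    fit, qc = tp.fit_aci(curve)
    kind = curve.curve_id.split("-qc-")[-1]
    flags = [name for name, v in [
        ("maxCi<700", qc.c1_max_ci_below_700),
        ("no-plateau", qc.c2_no_plateau),
        ("RMSE>6", qc.c3_rmse_above_6),
        ("bilinear", qc.c4_bilinear)] if v]
    verdict = "EXCLUDED" if qc.excluded else "retained"
    print(f"{kind:10s} method={fit.method:8s} rmse={fit.rmse:5.2f} "
          f"criteria={flags} -> {verdict}")
# A single tripped criterion keeps the curve; two or more exclude it.
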