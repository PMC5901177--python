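"""Model how photosynthetic capacity and respiration respond to temperature.

Fits curves for one design cell (5 tussocks x 15/20/25 degC), pools the
per-curve Vcmax estimates into an Arrhenius fit (rate at 25 degC plus an
activation energy), and fits the exponential respiration model whose b
coefficient gives the familiar Q10.
"""

import numpy as np

import tundraphys as tp

truth = tp.default_truth(seed=42)
ds = tp.generate_garden_dataset(truth, "TL")
cell_curves = [c for c in ds["curves"]
               if (c.ecotype, c.treatment) == ("CF", "ambient")]

points_v, points_rd = [], []
for curve in cell_curves:
    fit, qc = tp.fit_aci(curve)
    if qc.excluded:
        continue
    points_v.append((curve.tleaf_target, fit.Vcmax))
    points_rd.append((curve.tleaf_target, curve.Rd_measured))

arr = tp.fit_arrhenius_group(points_v)
print(f"Arrhenius fit of Vcmax, CF-ambient at TL ({arr.n} curves):")
print(f"  Vcmax(25) = {arr.k25:.1f} +/- {arr.k25_se:.1f} umol m-2 s-1 "
      f"(generating value {truth.cell('TL', 'CF', 'ambient').vcmax25})")
print(f"  Ea        = {arr.Ea:.1f} +/- {arr.Ea_se:.1f} kJ/mol "
      f"(generating value {truth.cell('TL', 'CF', 'ambient').ea_v / 1000})")
print(f"  model SE {arr.model_se:.2f}, R2adj {arr.r2_adj:.2f}, "
      f"F {arr.F:.1f}, p {arr.p:.4f}")

band = arr.confidence_band(np.array([15.0, 20.0, 25.0]))
print("  95% confidence band:")
for _, r in band.iterrows():
    print(f"    {r.tleaf:4.0f} degC: {r.fit:5.1f} "
          f"[{r.lower:5.1f}, {r.upper:5.1f}]")

resp = tp.fit_rd_exponential(points_rd)
q10_true = float(np.exp(10 * truth.cell("TL", "CF", "ambient").rd_b))
print(f"\nExponential Rd fit: a = {resp.a:.3f}, b = {resp.b:.4f} per degC")
print(f"  Q10 = exp(10 b) = {resp.Q10:.2f} (generating value {q10_true:.2f})")
# Q10 is the multiplicative increase in respiration per 10 degC of warming.
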