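"""Generate a synthetic catchment and inspect the simulated soil data.

Builds the reference configuration: a 110x110-cell DEM at 5 m resolution
(~30 ha, elevation 105-275 m), 67 SOC plots (55 with bulk density), and
noisy profile values at the five sampling increments.
"""

import numpy as np

from pedovox.synthetic import reference_catchment

cat = reference_catchment(seed=1)

print(f"DEM: {cat.dem.shape[0]}x{cat.dem.shape[1]} cells at "
      f"{cat.dem.cell_size_m:.0f} m, elevation "
      f"{cat.dem.values.min():.0f}-{cat.dem.values.max():.0f} m a.s.l.")
print(f"plots: {cat.soc.n_plots} SOC, {cat.bd.n_plots} with bulk density")
print(f"covariates: {len(cat.stack)} standardized multi-scale terrain layers")

mids = cat.soc.increments.mid_depths_cm
print("\nper-increment means (SOC in %, BD in g/cm^3):")
for j, d in enumerate(mids):
    bd = cat.bd.values[:, j].mean()
    print(f"  {d:5.1f} cm   SOC {cat.soc.values[:, j].mean():.2f}   BD {bd:.2f}")

print("\nSOC decreases and BD increases down the profile, inside the bounds")
print(f"SOC [{cat.soc.values.min():.2f}, {cat.soc.values.max():.2f}] %, "
      f"BD [{cat.bd.values.min():.2f}, {cat.bd.values.max():.2f}] g/cm^3 "
      "that the generator enforces.")
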