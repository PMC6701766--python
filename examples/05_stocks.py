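"""Compute SOC stocks from SOC and bulk-density voxel models.

Demonstrates the voxel stock formula (stock = SOC/100 * BD * cell_area * dz,
in g per voxel) and depth-interval aggregation to Mg per hectare, including
summation of pre-aggregated per-increment layer densities.
"""

import numpy as np

from pedovox.mapping import CoefficientFields, solve_voxels
from pedovox.stocks import aggregate_stock, layer_densities, voxel_stock

shape = (20, 20)
soc_fields = CoefficientFields("exp", {"c1": np.full(shape, 1.1),
                                       "c2": np.full(shape, -0.035)},
                               cv={}, fitted_coefficients=None)
bd_fields = CoefficientFields("log", {"c1": np.full(shape, 0.26),
                                      "c2": np.full(shape, 12.5)},
                              cv={}, fitted_coefficients=None)

soc = solve_voxels(soc_fields, 5, 50, 5, clamp_floor=0.0)
bd = solve_voxels(bd_fields, 5, 50, 5, clamp_floor=None, property_name="BD")
stock = voxel_stock(soc, bd)

print(f"voxel volume: {stock.voxel_volume_m3} m^3 "
      f"({stock.cell_size_cm:.0f} cm x {stock.cell_size_cm:.0f} cm x {stock.dz_cm:.0f} cm)")
print(f"surface voxel stock: {stock.values[0, 0, 0]:,.0f} g per voxel")

print("\nper-slab areal densities (Mg/ha):")
for depth, dens in layer_densities(stock).items():
    print(f"  slab ending at {depth:4.0f} cm: {dens:6.2f}")

total = aggregate_stock(stock, (5.0, 40.0))
top = aggregate_stock(stock, (5.0, 20.0))
sub = aggregate_stock(stock, (20.0, 40.0))
print(f"\n5-40 cm total: {total:.1f} Mg/ha = topsoil {top:.1f} + subsoil {sub:.1f}")
print("Aggregation is additive over depth, so any topsoil/subsoil split is exact.")

reported = [19.0, 14.7, 12.0, 8.9, 7.3]
print(f"\nsumming pre-aggregated per-increment densities {reported} "
      f"gives {aggregate_stock(reported):.1f} Mg/ha over 0-40 cm.")
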