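"""Generate a synthetic two-census stem-mapped plot and inspect it.

Builds the default 30-ha (500 x 600 m) plot: a 20-m corner elevation grid
and a stem table with positions, species, and DBH/height at both censuses.
"""

import scalewoods as sw

cfg = sw.SyntheticConfig(seed=1)
stems, grid = sw.generate_forest(cfg)

print(f"plot: {cfg.plot_x:g} x {cfg.plot_y:g} m "
      f"({cfg.plot_x * cfg.plot_y / 1e4:g} ha)")
print(f"elevation corners: {grid.nx} x {grid.ny} = {grid.nx * grid.ny} "
      f"({grid.n_cells} cells of {cfg.grid_spacing:g} m)")
print(f"elevation range: {grid.z.min():.1f} - {grid.z.max():.1f} m")
print(f"stems: {len(stems)} (census-1 live: {stems['dbh1_cm'].notna().sum()})")
print(stems["status"].value_counts().to_string())

allometry = sw.AllometryTable.default()
p = sw.quadrat_productivity(stems, cfg.plot_x * cfg.plot_y / 1e4, allometry)
print(f"\nwhole-plot AGB productivity: {p:.3f} Mg/ha/yr")
print("(net periodic annual increment of above-ground biomass, DBH >= 5 cm)")
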