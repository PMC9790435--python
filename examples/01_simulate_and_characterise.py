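"""Generate a small synthetic tropics and summarise its fire regimes.

Builds a 20 x 20 three-region lattice with five planted fire-regime
archetypes plus fire-free (NLSF) cells, computes the per-cell
12-characteristic table, and prints the regime-mean characteristics.
"""

import numpy as np

from fireregimes import generate_fire_archive, make_grid
from fireregimes.characteristics import CHARACTERISTIC_COLUMNS, characteristics_table

grid = make_grid(20, 20)
series, truth = generate_fire_archive(grid, years=14, seed=1)
chars = characteristics_table(series)

print(f"{grid.n_cells} cells, {series.n_years} years, "
      f"{int((truth.regime_label == 0).sum())} NLSF cells")
summary = chars[CHARACTERISTIC_COLUMNS].groupby(truth.regime_label).mean()
print(summary[["ba_year_mean", "ba_year_cv", "fsize_year_mean",
               "nfire_year_mean"]].round(2))
print("\nRows are planted regimes (0 = no landscape-scale fire): burned "
      "area rises and interannual variability falls along the planted "
      "low-variable -> high-stable gradient, with the largest fires in "
      "the high-stable regime.")
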