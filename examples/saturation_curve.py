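"""How many UMIs does deeper sequencing buy?

Builds a molecule table with realistic read multiplicities, thins it
binomially from 10% to 100% depth, and fits the saturation curve
y = a + b/(x + x0) to the mean-UMIs-versus-depth points.  The asymptote a
is the predicted library complexity per cell at infinite depth.
"""

import numpy as np
import pandas as pd

from onepotseq import fit_saturation, saturation_series

rng = np.random.default_rng(21)
n_cells, mol_per_cell = 50, 1500
rows = []
for i in range(n_cells):
    n_mol = rng.poisson(mol_per_cell)
    rows.append(pd.DataFrame({
        "cell_barcode": f"BC{i:03d}",
        "gene": rng.choice([f"g{j}" for j in range(200)], n_mol),
        "umi": [f"U{i:03d}_{k:05d}" for k in range(n_mol)],
        "reads": 1 + rng.poisson(3.0, n_mol),
    }))
umi_table = pd.concat(rows, ignore_index=True)

series = saturation_series(umi_table, np.arange(0.1, 1.01, 0.1),
                           seed=22, min_transcripts=500)
print(series.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

fit = fit_saturation(series["depth"], series["mean_umi"])
print(f"\nfit: a = {fit.a:.0f}, b = {fit.b:.3g}, x0 = {fit.x0:.0f}, rss = {fit.rss:.2f}")
print(f"predicted saturation level: {fit.a:.0f} UMIs per cell "
      f"(observed at full depth: {series['mean_umi'].iloc[-1]:.0f})")
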