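"""Choosing bead and cell loadings with the Poisson chamber model.

For 20,000 beads in a 12-well plate well (3.8 cm^2) and an effective
capture radius of 60 um, prints how cell yield, bead yield and the
multiplet rate among barcoded beads change with the number of input cells.
Cell yield depends only on bead density, which is why its column is flat.
"""

from onepotseq import DesignParams, design_metrics, rho_from_count

r_e = 60.0
rho_b = rho_from_count(20_000, well=12)

print("cells/well  lambda_c  cell_yield  bead_yield  multiplet_barcoded")
for n_cells in (1000, 2000, 4000, 8000, 12_000, 20_000):
    rho_c = rho_from_count(n_cells, well=12)
    m = design_metrics(DesignParams(rho_b=rho_b, rho_c=rho_c, r_e=r_e))
    print(
        f"{n_cells:10d}  {m.lambda_c:8.4f}  {m.cell_yield:10.4f}"
        f"  {m.bead_yield:10.4f}  {m.multiplet_barcoded:18.4f}"
    )

print(
    "\nmultiplet_barcoded is the fraction of sequenced (barcoded) beads whose\n"
    "transcripts come from two or more cells; it grows roughly as lambda_c/2\n"
    "at sparse loadings, which is the basis for picking a cell density."
)
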