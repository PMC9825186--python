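"""Recovering the expression matrix from error-bearing reads.

Generates a ground-truth UMI count matrix over a minimum-distance-3
barcode whitelist, expands it into reads with 1% per-base substitution
and 0.1% indel rates, collapses barcodes and UMIs with the directional
single-error rule, and scores the result against the ground truth.
"""

import numpy as np

from onepotseq import (
    MatrixBundle,
    barcode_assignment_accuracy,
    build_dge,
    gen_reads,
    gen_whitelist,
)
import pandas as pd

rng = np.random.default_rng(11)
whitelist = gen_whitelist(100, length=12, min_distance=3, seed=12)
truth = MatrixBundle(
    matrix=rng.poisson(8.0, size=(100, 25)),
    barcodes=np.array(whitelist, dtype=object),
    genes=pd.DataFrame({"gene": [f"g{j:03d}" for j in range(25)],
                        "species": ["A"] * 25}),
)

reads = gen_reads(truth, substitution_rate=0.01, indel_rate=0.001,
                  seed=13, mean_reads_per_umi=2.0)
n_corrupted = int((reads["cell_barcode"] != reads["true_barcode"]).sum())
print(f"{len(reads)} reads, {n_corrupted} with a corrupted barcode "
      f"({n_corrupted / len(reads):.1%})")

dge, result = build_dge(reads)
accuracy = barcode_assignment_accuracy(reads, result)
print(f"observed barcodes: {len(result.mapping)}, "
      f"canonical after collapse: {len(result.merged_counts)} "
      f"({result.n_merged} merged)")
print(f"reads assigned to their true barcode: {accuracy:.2%}")
print(f"total UMIs: truth {truth.matrix.sum()}, recovered {dge.matrix.sum()}")
print("\nThe collapse absorbs single-base error halos back into the true\n"
      "barcodes without merging genuinely distinct whitelist barcodes.")
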