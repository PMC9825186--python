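"""Mixed-species ("barnyard") quality statistics.

Mixing cells of two species with disjoint gene sets makes multiplets and
contamination directly visible: a bead barcode whose UMIs split across both
species was exposed to more than one cell.  A barcode with more than
``min_transcripts`` total UMIs is called a cell; a called cell is assigned
to a species when its transcript ratio passes a strict threshold (ratio of
species-a transcripts > hi → a, < lo → b, anything else — including exactly
hi or lo — is mixed).  Species purity is the larger of the two ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MatrixBundle

__all__ = [
    "call_cells",
    "species_counts",
    "classify_species",
    "summarize",
    "knee_curve",
    "barnyard_report",
]


def call_cells(bundle: MatrixBundle, min_transcripts: int = 500) -> np.ndarray:
    """Barcodes with strictly more than ``min_transcripts`` total UMIs."""
    totals = bundle.totals_per_barcode()
    return bundle.barcodes[totals > min_transcripts]


def species_counts(bundle: MatrixBundle, barcodes=None) -> pd.DataFrame:
    """Per-barcode UMI totals split by species (one column per species)."""
    species = bundle.genes["species"].to_numpy()
    labels = sorted(pd.unique(species))
    data = {}
    for sp in labels:
        cols = np.nonzero(species == sp)[0]
        data[sp] = np.asarray(bundle.matrix[:, cols].sum(axis=1)).ravel()
    out = pd.DataFrame(data, index=pd.Index(bundle.barcodes, name="barcode"))
    if barcodes is not None:
        out = out.loc[list(barcodes)]
    return out


def classify_species(
    counts: pd.DataFrame, hi: float = 0.9, lo: float = 0.1
) -> pd.DataFrame:
    """Classify called barcodes by their species transcript ratio.

    ``counts`` must have exactly two species columns (first column is
    species a).  Strict thresholds: ratio_a > hi → species a, ratio_a < lo →
    species b, otherwise mixed.  Adds ratio_a, purity and class columns.
    """
    if counts.shape[1] != 2:
        raise ValueError(
            f"expected exactly two species columns, got {list(counts.columns)}"
        )
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("thresholds must satisfy 0 <= lo < hi <= 1")
    sp_a, sp_b = counts.columns
    total = counts[sp_a] + counts[sp_b]
    if (total == 0).any():
        zero = counts.index[total == 0].tolist()
        raise ValueError(
            f"barcodes with zero transcripts should have been filtered: {zero[:5]}"
        )
    ratio_a = counts[sp_a] / total
    cls = np.where(ratio_a > hi, sp_a, np.where(ratio_a < lo, sp_b, "mixed"))
    out = counts.copy()
    out["ratio_a"] = ratio_a
    out["purity"] = np.maximum(ratio_a, 1.0 - ratio_a)
    out["class"] = cls
    return out


def summarize(calls: pd.DataFrame, n_input_cells: int) -> dict:
    """Multiplet rate, cell yield and per-class counts from classified calls.

    multiplet_rate = mixed barcodes / called barcodes;
    cell_yield = called barcodes / input cells.
    """
    if n_input_cells <= 0:
        raise ValueError("n_input_cells must be > 0")
    if "class" not in calls.columns:
        raise ValueError("calls must come from classify_species")
    n_called = len(calls)
    class_counts = calls["class"].value_counts().to_dict()
    n_mixed = class_counts.get("mixed", 0)
    return {
        "n_called": n_called,
        "multiplet_rate": n_mixed / n_called if n_called else 0.0,
        "cell_yield": n_called / n_input_cells,
        "class_counts": class_counts,
    }


def knee_curve(bundle: MatrixBundle) -> pd.DataFrame:
    """Cumulative UMI fraction versus barcode rank (descending totals)."""
    totals = np.sort(bundle.totals_per_barcode())[::-1]
    if len(totals) == 0:
        raise ValueError("empty matrix has no knee curve")
    grand = totals.sum()
    cumulative = np.cumsum(totals) / grand if grand > 0 else np.zeros_like(totals, float)
    return pd.DataFrame(
        {"rank": np.arange(1, len(totals) + 1), "cumulative_fraction": cumulative}
    )


def barnyard_report(
    bundle: MatrixBundle,
    n_input_cells: int,
    min_transcripts: int = 500,
    hi: float = 0.9,
    lo: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Full barnyard QC: call cells, classify, summarize.

    Returns the per-barcode call table (sub-threshold barcodes included with
    class "sub-threshold") and the summary dict computed over called cells
    only.
    """
    counts = species_counts(bundle)
    totals = counts.sum(axis=1)
    called_mask = totals > min_transcripts
    nonzero = totals > 0
    classified = classify_species(counts[called_mask], hi=hi, lo=lo)
    summary = summarize(classified, n_input_cells)
    rest = counts[~called_mask & nonzero].copy()
    if len(rest):
        ra = rest.iloc[:, 0] / (rest.iloc[:, 0] + rest.iloc[:, 1])
        rest["ratio_a"] = ra
        rest["purity"] = np.maximum(ra, 1.0 - ra)
        rest["class"] = "sub-threshold"
    table = pd.concat([classified, rest]) if len(rest) else classified
    return table, summary
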