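"""Perturbation-signature scoring, reference-profile correlation and
cell-type enrichment folds.

The signature score summarises a transcriptional response per cell: genes
with average log count below a floor are dropped, the remaining genes'
log(1 + count) values are z-scored across cells, and each cell's induced
(or suppressed) score is the mean z over the corresponding gene list —
the pathway-activity readout used to quantify drug response in single
cells.  Group mean profiles can be matched to user-supplied bulk reference
profiles by Pearson correlation, and cell-type composition shifts are
reported as fold changes against a baseline sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import MatrixBundle

__all__ = [
    "signature_score",
    "correlate_reference",
    "enrichment_fold",
]


def _log1p_dense(bundle: MatrixBundle) -> np.ndarray:
    return np.log1p(bundle.to_dense().astype(float))


def signature_score(
    bundle: MatrixBundle,
    induced_genes,
    suppressed_genes,
    min_avg_log_count: float = 0.1,
    normalization: str = "zscore",
) -> pd.DataFrame:
    """Per-cell induced and suppressed signature scores.

    Genes whose mean log(1 + count) across cells is below
    ``min_avg_log_count`` are removed; surviving genes are normalised across
    cells ("zscore" by default, "minmax" as an alternative); each cell's
    score is the mean normalised expression over the gene list.  Zero-
    variance genes are excluded with a warning.
    """
    if normalization not in ("zscore", "minmax"):
        raise ValueError(f"unknown normalization {normalization!r}")
    induced = list(dict.fromkeys(induced_genes))
    suppressed = list(dict.fromkeys(suppressed_genes))
    if not induced or not suppressed:
        raise ValueError("both gene lists must be non-empty")

    log_counts = _log1p_dense(bundle)
    genes = bundle.genes["gene"].to_numpy(dtype=object)
    keep = log_counts.mean(axis=0) >= min_avg_log_count
    # a gene identical in every cell has no variance to standardise
    constant = keep & (log_counts.max(axis=0) - log_counts.min(axis=0) == 0)
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant-expression gene(s) "
            "from normalisation",
            stacklevel=2,
        )
        keep &= ~constant
    kept_genes = set(genes[keep])

    X = log_counts[:, keep]
    if normalization == "zscore":
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
    else:
        span = X.max(axis=0) - X.min(axis=0)
        Z = (X - X.min(axis=0)) / span
    col = {g: j for j, g in enumerate(genes[keep])}

    scores = {}
    for name, gene_list in (("induced_score", induced), ("suppressed_score", suppressed)):
        present = [g for g in gene_list if g in kept_genes]
        if not present:
            raise ValueError(
                f"no {name.split('_')[0]} genes survive the expression filter"
            )
        scores[name] = Z[:, [col[g] for g in present]].mean(axis=1)
    return pd.DataFrame(
        {"cell": bundle.barcodes, **scores}
    ).set_index("cell")


def correlate_reference(
    group_means: pd.DataFrame, reference_profiles: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Pearson correlation of each group's mean profile with each reference.

    Both inputs are genes × columns tables indexed by gene identifier; the
    correlation is computed on the intersected gene set (≥ 3 genes
    required).  Returns (groups × references correlation table, number of
    shared genes).
    """
    shared = group_means.index.intersection(reference_profiles.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared genes between groups and references; "
            "need at least 3"
        )
    g = group_means.loc[shared].to_numpy(dtype=float)
    r = reference_profiles.loc[shared].to_numpy(dtype=float)
    gc = g - g.mean(axis=0)
    rc = r - r.mean(axis=0)
    denom = np.outer(np.linalg.norm(gc, axis=0), np.linalg.norm(rc, axis=0))
    corr = (gc.T @ rc) / denom
    return (
        pd.DataFrame(corr, index=group_means.columns, columns=reference_profiles.columns),
        len(shared),
    )


def enrichment_fold(frequencies: dict, baseline_frequencies: dict) -> pd.Series:
    """Fold change of each cell type's frequency against a baseline sample.

    fold = sample fraction / baseline fraction.  Types with baseline 0 and a
    nonzero sample fraction are infinite enrichment: flagged with a warning
    and excluded from the numeric output.
    """
    folds = {}
    infinite = []
    for cell_type, base in baseline_frequencies.items():
        freq = frequencies.get(cell_type, 0.0)
        if base > 0:
            folds[cell_type] = freq / base
        elif freq > 0:
            infinite.append(cell_type)
    extra_inf = [
        t for t, f in frequencies.items() if f > 0 and t not in baseline_frequencies
    ]
    infinite.extend(extra_inf)
    if infinite:
        warnings.warn(
            f"infinite enrichment (baseline 0) excluded for: {sorted(infinite)}",
            stacklevel=2,
        )
    return pd.Series(folds, name="fold_change")
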