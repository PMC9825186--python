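"""Depth subsampling and saturation-curve fitting.

Sequencing deeper recovers more distinct molecules per cell, saturating as
duplicate reads accumulate.  Reads are thinned binomially (each read kept
independently with the chosen fraction; a UMI with multiplicity m survives
with probability 1 − (1 − f)^m) and the mean-UMIs-versus-depth points are
fit with the hyperbolic saturation curve

    y = a + b / (x + x0)

whose asymptote ``a`` is the predicted saturation level.  (``x0`` is the
curve's depth offset, often written c.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SaturationFitResult",
    "SaturationFitError",
    "umi_table_from_reads",
    "subsample_reads",
    "saturation_series",
    "fit_saturation",
]

UMI_TABLE_COLUMNS = ["cell_barcode", "gene", "umi", "reads"]


class SaturationFitError(RuntimeError):
    """Raised when the saturation fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, best_params=None, diagnostics: str = ""):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class SaturationFitResult:
    """Fitted parameters of y = a + b/(x + x0)."""

    a: float
    b: float
    x0: float
    rss: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a + self.b / (x + self.x0)


def umi_table_from_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse read records to one row per molecule with its multiplicity."""
    required = {"cell_barcode", "gene", "umi"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"read table is missing columns: {sorted(missing)}")
    out = (
        reads.groupby(["cell_barcode", "gene", "umi"], sort=True)
        .size()
        .rename("reads")
        .reset_index()
    )
    return out


def subsample_reads(
    umi_table: pd.DataFrame, fraction: float, seed: int | None = None
) -> pd.DataFrame:
    """Binomially thin each molecule's reads; drop molecules with none left.

    Equivalent to keeping every read independently with probability
    ``fraction`` — two-stage thinning at f1 then f2 matches one stage at
    f1·f2 in distribution.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction!r}")
    missing = [c for c in UMI_TABLE_COLUMNS if c not in umi_table.columns]
    if missing:
        raise ValueError(f"UMI table is missing columns: {missing}")
    out = umi_table.copy()
    if fraction == 1.0:
        return out
    if fraction == 0.0:
        return out.iloc[0:0]
    rng = np.random.default_rng(seed)
    surviving = rng.binomial(out["reads"].to_numpy(), fraction)
    out["reads"] = surviving
    return out[out["reads"] > 0].reset_index(drop=True)


def _mean_over(umi_table: pd.DataFrame, barcodes: np.ndarray) -> tuple[float, float]:
    """(mean reads, mean UMIs) per barcode over a frozen barcode set."""
    by_bc_reads = umi_table.groupby("cell_barcode")["reads"].sum()
    by_bc_umis = umi_table.groupby("cell_barcode").size()
    reads = by_bc_reads.reindex(barcodes, fill_value=0).to_numpy(dtype=float)
    umis = by_bc_umis.reindex(barcodes, fill_value=0).to_numpy(dtype=float)
    return float(reads.mean()), float(umis.mean())


def saturation_series(
    umi_table: pd.DataFrame,
    fractions,
    seed: int | None = None,
    min_transcripts: int = 500,
    refit_cells: bool = False,
) -> pd.DataFrame:
    """Mean depth and mean UMIs per cell across subsampling fractions.

    Cells are the barcodes with more than ``min_transcripts`` distinct UMIs
    at full depth; this set is frozen across fractions unless
    ``refit_cells`` re-selects it at each depth.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    full_umis = umi_table.groupby("cell_barcode").size()
    frozen = full_umis.index[full_umis > min_transcripts].to_numpy()
    if len(frozen) == 0:
        raise ValueError(
            f"no barcode exceeds {min_transcripts} UMIs at full depth"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        thinned = subsample_reads(umi_table, float(f), seed=int(rng.integers(2**31)))
        if refit_cells:
            sub_umis = thinned.groupby("cell_barcode").size()
            cells = sub_umis.index[sub_umis > min_transcripts].to_numpy()
            if len(cells) == 0:
                rows.append((f, 0.0, 0.0))
                continue
        else:
            cells = frozen
        depth, umis = _mean_over(thinned, cells)
        rows.append((f, depth, umis))
    return pd.DataFrame(rows, columns=["fraction", "depth", "mean_umi"])


def fit_saturation(depths, mean_values) -> SaturationFitResult:
    """Nonlinear least squares for y = a + b/(x + x0).

    Initialisation: a0 = 1.05·max(y), x0_0 = median(x), b0 from solving the
    first data point.  A constant series short-circuits to a = y, b = 0 with
    a degenerate flag.
    """
    x = np.asarray(depths, dtype=float)
    y = np.asarray(mean_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("depths and mean_values must be matching 1-D arrays")
    if len(x) < 4:
        raise ValueError("at least 4 points are required")
    if len(np.unique(x)) != len(x):
        raise ValueError("depths must be distinct")

    if np.allclose(y, y[0], rtol=0, atol=1e-12 * max(1.0, abs(float(y[0])))):
        return SaturationFitResult(
            a=float(y[0]), b=0.0, x0=float(np.median(x)), rss=0.0,
            flags=("degenerate_constant",),
        )

    a0 = 1.05 * float(np.max(y))
    x00 = float(np.median(x))
    b0 = (float(y[0]) - a0) * (float(x[0]) + x00)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, x0 = theta
        return a + b / (x + x0) - y

    res = optimize.least_squares(
        residuals,
        x0=np.array([a0, b0, x00]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        method="lm",
    )
    if not res.success:
        raise SaturationFitError(
            f"saturation fit did not converge: {res.message}",
            best_params=tuple(res.x),
            diagnostics=f"status={res.status}, cost={res.cost:.6g}, nfev={res.nfev}",
        )
    a, b, x0 = map(float, res.x)
    flags: tuple[str, ...] = ()
    fitted = a + b / (x + x0)
    if np.any(fitted < 0) or x0 <= -float(np.min(x)):
        flags = ("curve_outside_valid_range",)
    rss = float(np.sum(res.fun**2))
    return SaturationFitResult(a=a, b=b, x0=x0, rss=rss, flags=flags)
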