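"""Poisson loading model for compartment-free single-cell capture.

Beads and cells settle at random positions on a 2-D surface.  A lysed cell
creates a transient reaction chamber of effective radius ``r_e``; the number
of beads (or cells) inside a chamber is Poisson with mean λ = ρ·π·r_e².
Closed forms follow for the cell capture efficiency, the fraction of beads
that become barcoded, and the multiplet rate — overall and conditioned on a
bead being barcoded:

    P(cell yield)            = 1 − exp(−λ_b),     λ_b = ρ_b π r_e²
    P(bead yield)            = 1 − exp(−λ_c),     λ_c = ρ_c π r_e²
    P(multiplet)             = 1 − exp(−λ_c)(1 + λ_c)
    P(multiplet | barcoded)  = 1 − λ_c exp(−λ_c) / (1 − exp(−λ_c))

Cell yield depends only on bead density and r_e, never on cell density.
The module also estimates r_e from observed multiplet counts at several
cell densities by binomial maximum likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DesignParams",
    "DesignMetrics",
    "EffectiveRadiusFit",
    "lambda_from_density",
    "multiplet_among_barcoded",
    "design_metrics",
    "fit_effective_radius",
    "rho_from_count",
    "WELL_AREAS_CM2",
]

#: growth-area presets (cm²) for converting cells-per-well to surface density
WELL_AREAS_CM2 = {6: 9.6, 12: 3.8, 24: 1.9, 48: 0.95, 96: 0.32}

CM2_TO_UM2 = 1e8


@dataclass(frozen=True)
class DesignParams:
    """Surface densities and effective capture radius.

    rho_b, rho_c in beads (cells) per μm²; r_e in μm.
    """

    rho_b: float
    rho_c: float
    r_e: float

    def __post_init__(self) -> None:
        for name in ("rho_b", "rho_c", "r_e"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class DesignMetrics:
    lambda_b: float
    lambda_c: float
    cell_yield: float
    bead_yield: float
    multiplet_all: float
    multiplet_barcoded: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lambda_b": self.lambda_b,
            "lambda_c": self.lambda_c,
            "cell_yield": self.cell_yield,
            "bead_yield": self.bead_yield,
            "multiplet_all": self.multiplet_all,
            "multiplet_barcoded": self.multiplet_barcoded,
        }


def lambda_from_density(rho: float, r_e: float) -> float:
    """Expected occupants per chamber: λ = ρ·π·r_e²."""
    if not math.isfinite(rho) or rho < 0:
        raise ValueError(f"rho must be finite and >= 0, got {rho!r}")
    if not math.isfinite(r_e) or r_e < 0:
        raise ValueError(f"r_e must be finite and >= 0, got {r_e!r}")
    return rho * math.pi * r_e * r_e


def rho_from_count(n: float, well: int | None = None, area_cm2: float | None = None) -> float:
    """Surface density (per μm²) of ``n`` objects spread over a well.

    Either a plate-format preset (``well``, e.g. 12 for a 12-well plate with
    3.8 cm² growth area) or an explicit ``area_cm2`` must be given.
    """
    if area_cm2 is None:
        if well is None:
            raise ValueError("give either a well-plate format or an explicit area")
        try:
            area_cm2 = WELL_AREAS_CM2[well]
        except KeyError:
            raise ValueError(f"no area preset for {well}-well plates") from None
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    return n / (area_cm2 * CM2_TO_UM2)


def multiplet_among_barcoded(lam: float) -> float:
    """P(≥2 cells in the chamber | ≥1 cell) for a Poisson(λ) occupancy.

    = (1 − e^{−λ}(1 + λ)) / (1 − e^{−λ}); the λ → 0 limit is λ/2 and is
    returned exactly at λ = 0.  Computed with expm1 so the small-λ regime
    is accurate in floating point.
    """
    if not math.isfinite(lam) or lam < 0:
        raise ValueError(f"lambda must be finite and >= 0, got {lam!r}")
    if lam == 0.0:
        return 0.0
    denom = -math.expm1(-lam)  # 1 - e^{-lam}
    num = denom - lam * math.exp(-lam)
    return num / denom


def design_metrics(params: DesignParams) -> DesignMetrics:
    """All closed-form design probabilities for the given densities."""
    lam_b = lambda_from_density(params.rho_b, params.r_e)
    lam_c = lambda_from_density(params.rho_c, params.r_e)
    cell_yield = -math.expm1(-lam_b)
    bead_yield = -math.expm1(-lam_c)
    multiplet_all = -math.expm1(-lam_c) - lam_c * math.exp(-lam_c)
    return DesignMetrics(
        lambda_b=lam_b,
        lambda_c=lam_c,
        cell_yield=cell_yield,
        bead_yield=bead_yield,
        multiplet_all=multiplet_all,
        multiplet_barcoded=multiplet_among_barcoded(lam_c),
    )


@dataclass(frozen=True)
class EffectiveRadiusFit:
    """Maximum-likelihood estimate of the effective capture radius."""

    r_e: float
    se: float
    nll: float
    estimator: str
    flags: tuple[str, ...] = field(default_factory=tuple)


def _as_observation_arrays(
    observations: Iterable[Sequence[float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows = [tuple(map(float, row)) for row in observations]
    if not rows:
        raise ValueError("at least one observation is required")
    rho, k, n = (np.array(col) for col in zip(*rows))
    if np.any(rho < 0):
        raise ValueError("cell densities must be >= 0")
    if np.any(n <= 0):
        raise ValueError("barcoded-bead totals must be > 0")
    if np.any((k < 0) | (k > n)):
        raise ValueError("multiplet counts must lie in [0, total]")
    return rho, k, n


def fit_effective_radius(
    observations: Iterable[Sequence[float]],
    estimator: str = "mle",
    bounds: tuple[float, float] = (1e-2, 1e4),
) -> EffectiveRadiusFit:
    """Estimate r_e from (rho_c, multiplets_observed, barcoded_beads_total) rows.

    The default estimator minimises the binomial negative log-likelihood of
    multiplets_observed ~ Binomial(total, P(multiplet | barcoded; rho_c, r_e));
    ``estimator="wls"`` minimises the total-weighted squared error on the
    observed proportions instead.  The standard error comes from the observed
    information (numerical second derivative at the optimum).
    """
    rho, k, n = _as_observation_arrays(observations)
    flags: list[str] = []
    if len(np.unique(rho[rho > 0])) < 2:
        flags.append("single_density")
    if np.all(k == 0):
        flags.append("all_zero_multiplets")

    def p_of(r_e: float) -> np.ndarray:
        return np.array(
            [multiplet_among_barcoded(lambda_from_density(r, r_e)) for r in rho]
        )

    if estimator == "mle":

        def objective(log_re: float) -> float:
            p = np.clip(p_of(math.exp(log_re)), 1e-300, 1 - 1e-15)
            return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    elif estimator == "wls":

        def objective(log_re: float) -> float:
            p = p_of(math.exp(log_re))
            return float(np.sum(n * (k / n - p) ** 2))

    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    res = optimize.minimize_scalar(
        objective,
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    r_hat = math.exp(res.x)
    if "all_zero_multiplets" in flags:
        # likelihood is monotone decreasing in r_e: report the boundary
        r_hat = bounds[0]
        flags.append("lower_bound_estimate")

    # observed information by central difference on the r_e scale
    h = max(1e-4 * r_hat, 1e-6)

    def nll_re(r_e: float) -> float:
        return objective(math.log(r_e))

    info = (nll_re(r_hat + h) - 2.0 * nll_re(r_hat) + nll_re(r_hat - h)) / (h * h)
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    return EffectiveRadiusFit(
        r_e=float(r_hat),
        se=float(se),
        nll=float(nll_re(r_hat)),
        estimator=estimator,
        flags=tuple(flags),
    )
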