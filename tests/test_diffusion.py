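"""Diffusion of mRNA from a uniformly loaded sphere.

The implementation integrates the image-source integral by quadrature; the
tests check it against the independent erf closed form of the same initial
value problem, against a particle random-walk Monte Carlo, and against the
Maxwell radial CDF in the point-source limit.
"""

import math

import numpy as np
import pytest
from scipy import optimize, special

from onepotseq.diffusion import (
    DiffusionParams,
    concentration_at,
    cumulative_fraction,
    diffusion_distance,
    droplet_comparison,
    radial_profile,
)

PARAMS = DiffusionParams(D=1.0, R=5.0, c0=1.2)


def erf_solution(params, r, t):
    """Closed form of the sphere-source diffusion profile (independent oracle).

    Obtained by integrating the image-source integral analytically:
    c = c0/2·[erf((R−r)/s) + erf((R+r)/s)]
      + c0·s/(2r√π)·[exp(−((R+r)/s)²) − exp(−((R−r)/s)²)],  s = 2√(Dt).
    """
    s = 2.0 * math.sqrt(params.D * t)
    if r < 1e-4 * s:  # analytic r -> 0 limit avoids catastrophic cancellation
        return params.c0 * (
            special.erf(params.R / s)
            - 2.0 * params.R / (s * math.sqrt(math.pi)) * math.exp(-((params.R / s) ** 2))
        )
    term1 = 0.5 * (special.erf((params.R - r) / s) + special.erf((params.R + r) / s))
    term2 = (
        s
        / (2.0 * r * math.sqrt(math.pi))
        * (math.exp(-(((params.R + r) / s) ** 2)) - math.exp(-(((params.R - r) / s) ** 2)))
    )
    return params.c0 * (term1 + term2)


def maxwell_percentile(dt_product, fraction):
    """Radius containing `fraction` of mass for a point source (Maxwell CDF)."""
    sigma = math.sqrt(2.0 * dt_product)

    def cdf(x):
        return special.erf(x / (sigma * math.sqrt(2))) - math.sqrt(2 / math.pi) * (
            x / sigma
        ) * math.exp(-(x**2) / (2 * sigma**2))

    return optimize.brentq(lambda x: cdf(x) - fraction, 1e-3, 100 * sigma)


class TestConcentration:
    @pytest.mark.parametrize("r", [0.0, 0.5, 2.0, 5.0, 10.0, 25.0, 60.0])
    @pytest.mark.parametrize("t", [1.0, 30.0, 300.0])
    def test_quadrature_matches_erf_closed_form(self, r, t):
        assert concentration_at(PARAMS, r, t) == pytest.approx(
            erf_solution(PARAMS, r, t), rel=1e-7, abs=1e-15
        )

    def test_initial_condition(self):
        assert concentration_at(PARAMS, 1.0, 0.0) == 1.2
        assert concentration_at(PARAMS, 100.0, 0.0) == 0.0
        # t -> 0+ approaches the same values
        assert concentration_at(PARAMS, 1.0, 1e-6) == pytest.approx(1.2, rel=1e-6)
        assert concentration_at(PARAMS, 100.0, 1e-6) == pytest.approx(0.0, abs=1e-12)

    def test_matches_particle_random_walk(self):
        """~1e6 particles started uniformly in the sphere, free Gaussian
        displacement after t=300 s; radial shell density vs the quadrature."""
        rng = np.random.default_rng(12345)
        n = 1_000_000
        # uniform in the sphere by radius inversion
        radius = PARAMS.R * rng.random(n) ** (1.0 / 3.0)
        direction = rng.standard_normal((n, 3))
        direction /= np.linalg.norm(direction, axis=1)[:, None]
        pos = radius[:, None] * direction
        t = 300.0
        pos += rng.standard_normal((n, 3)) * math.sqrt(2.0 * PARAMS.D * t)
        r_lo, r_hi = 19.5, 20.5
        dist = np.linalg.norm(pos, axis=1)
        count = int(((dist >= r_lo) & (dist < r_hi)).sum())
        shell_volume = 4.0 / 3.0 * math.pi * (r_hi**3 - r_lo**3)
        p_hat = count / n
        conc_mc = p_hat / shell_volume * PARAMS.total_mass
        se = math.sqrt(p_hat * (1 - p_hat) / n) / shell_volume * PARAMS.total_mass
        assert abs(concentration_at(PARAMS, 20.0, t) - conc_mc) < 4 * se

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            DiffusionParams(D=-1.0)
        with pytest.raises(ValueError):
            DiffusionParams(c0=float("nan"))
        with pytest.raises(ValueError):
            concentration_at(PARAMS, -1.0, 10.0)
        with pytest.raises(ValueError):
            concentration_at(PARAMS, 1.0, -10.0)


class TestCumulativeFraction:
    @pytest.mark.parametrize("t", [1.0, 10.0, 60.0, 300.0, 900.0])
    def test_mass_conserved(self, t):
        r_far = PARAMS.R + 12.0 * math.sqrt(2.0 * PARAMS.D * t)
        assert cumulative_fraction(PARAMS, r_far, t) == pytest.approx(1.0, rel=1e-3)

    def test_monotone_in_r(self):
        radii = np.linspace(0.5, 120.0, 40)
        fractions = [cumulative_fraction(PARAMS, r, 300.0) for r in radii]
        assert np.all(np.diff(fractions) >= -1e-12)

    def test_initial_condition_is_volume_fraction(self):
        assert cumulative_fraction(PARAMS, 5.0, 0.0) == 1.0
        assert cumulative_fraction(PARAMS, 2.5, 0.0) == pytest.approx(0.125)
        assert cumulative_fraction(PARAMS, 50.0, 0.0) == 1.0

    def test_point_source_limit_matches_maxwell_cdf(self):
        """Near-point source: 90% radius equals the Maxwell 90th percentile."""
        tiny = DiffusionParams(D=1.0, R=0.01, c0=1.0)
        expected = maxwell_percentile(300.0, 0.9)
        x = 2.5 * math.sqrt(2.0 * 300.0)
        assert cumulative_fraction(tiny, x, 300.0) == pytest.approx(0.9, abs=2e-3)
        assert diffusion_distance(tiny, 300.0, 0.9) == pytest.approx(expected, rel=5e-3)


class TestDiffusionDistance:
    def test_ninety_percent_radius_after_five_minutes(self):
        """An independent trapezoid integration of the erf closed form gives
        the same 90%-mass radius as quadrature + root finding."""
        t = 300.0
        grid = np.linspace(1e-3, 200.0, 8001)
        conc = np.array([erf_solution(PARAMS, r, t) for r in grid])
        mass = np.concatenate(
            [[0.0], np.cumsum(
                0.5 * np.diff(grid) * (4 * np.pi) * (
                    grid[:-1] ** 2 * conc[:-1] + grid[1:] ** 2 * conc[1:]
                )
            )]
        ) / PARAMS.total_mass
        oracle = float(np.interp(0.9, mass, grid))
        assert diffusion_distance(PARAMS, t, 0.9) == pytest.approx(oracle, rel=1e-3)

    def test_depends_only_on_dt_product(self):
        fast = DiffusionParams(D=4.0, R=5.0, c0=1.2)
        assert diffusion_distance(fast, 75.0, 0.9) == pytest.approx(
            diffusion_distance(PARAMS, 300.0, 0.9), rel=1e-8
        )

    def test_monotone_in_time(self):
        distances = [diffusion_distance(PARAMS, t) for t in (30.0, 100.0, 300.0, 900.0)]
        assert np.all(np.diff(distances) > 0)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            diffusion_distance(PARAMS, 300.0, fraction=1.2)
        with pytest.raises(ValueError):
            diffusion_distance(PARAMS, 0.0, fraction=0.9)


class TestDropletComparison:
    def test_identical_volumes_at_time_zero(self):
        radius = 10.0
        vol_nl = 4.0 / 3.0 * math.pi * radius**3 / 1e6
        assert droplet_comparison(PARAMS, radius, 0.0, vol_nl) == pytest.approx(1.0)

    def test_consistent_with_cumulative_fraction(self):
        frac = cumulative_fraction(PARAMS, 40.0, 300.0)
        expected = frac * 1e6 / (4.0 / 3.0 * math.pi * 40.0**3)
        assert droplet_comparison(PARAMS, 40.0, 300.0, 1.0) == pytest.approx(expected)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            droplet_comparison(PARAMS, 40.0, 300.0, 0.0)


def test_radial_profile_validates_grid():
    prof = radial_profile(PARAMS, np.linspace(1.0, 50.0, 10), 60.0)
    assert prof.concentrations.shape == (10,)
    assert np.all(np.diff(prof.concentrations) < 0)  # decreasing away from the cell
    with pytest.raises(ValueError):
        radial_profile(PARAMS, np.array([3.0, 2.0, 1.0]), 60.0)
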