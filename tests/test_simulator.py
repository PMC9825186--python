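"""Spatial Monte-Carlo capture simulator versus the Poisson closed forms."""

import math

import numpy as np
import pytest
from scipy import stats

from onepotseq.design import DesignParams, design_metrics
from onepotseq.simulate import (
    CaptureConfig,
    Layout,
    TranscriptModel,
    empirical_stats,
    make_layout,
    place_uniform,
    simulate_experiment,
)
from onepotseq.synth import gen_profiles

PROFILES = gen_profiles(20, 2, dispersion=1.0, seed=101, species_names=["human", "mouse"])


def torus_layout(n_beads, n_cells, lam, r_e=60.0, seed=0):
    """Square torus whose area makes both lambda_b and lambda_c equal lam."""
    area = n_beads * math.pi * r_e**2 / lam
    side = math.sqrt(area)
    return make_layout(
        n_beads, n_cells, side, side,
        {"human": 0.5, "mouse": 0.5}, boundary="torus", seed=seed,
    ), side


class TestPlacement:
    def test_empty_and_deterministic(self):
        assert place_uniform(0, 100.0, 100.0, seed=1).shape == (0, 2)
        a = place_uniform(1000, 50.0, 80.0, seed=42)
        b = place_uniform(1000, 50.0, 80.0, seed=42)
        np.testing.assert_array_equal(a, b)
        assert a[:, 0].max() < 50.0 and a[:, 1].max() < 80.0

    def test_uniformity_chi_square(self):
        xy = place_uniform(10_000, 1000.0, 1000.0, seed=3)
        counts, *_ = np.histogram2d(
            xy[:, 0], xy[:, 1], bins=10, range=[[0, 1000], [0, 1000]]
        )
        stat, p = stats.chisquare(counts.ravel())
        assert p > 0.001


class TestSimulateExperiment:
    def test_reproducible_bit_identical(self):
        layout, _ = torus_layout(500, 500, 0.3, seed=5)
        cap = CaptureConfig(r_e=60.0, seed=9)
        b1, t1 = simulate_experiment(layout, cap, PROFILES, TranscriptModel(mean=100))
        b2, t2 = simulate_experiment(layout, cap, PROFILES, TranscriptModel(mean=100))
        assert (b1.matrix != b2.matrix).nnz == 0
        assert t1.equals(t2)

    def test_zero_radius_means_zero_counts(self):
        layout, _ = torus_layout(200, 200, 0.3, seed=6)
        cap = CaptureConfig(r_e=0.0, ambient_fraction=0.0, seed=1)
        bundle, truth = simulate_experiment(layout, cap, PROFILES)
        assert bundle.matrix.sum() == 0
        assert len(truth) == 0

    def test_single_cell_single_bead_identity(self):
        layout = Layout(
            width=500.0, height=500.0,
            bead_xy=np.array([[100.0, 100.0]]),
            cell_xy=np.array([[110.0, 100.0]]),
            cell_species=np.array(["human"], dtype=object),
            boundary="hard",
        )
        cap = CaptureConfig(r_e=60.0, capture_efficiency=1.0, ambient_fraction=0.0, seed=2)
        bundle, truth = simulate_experiment(
            layout, cap, PROFILES, TranscriptModel(mean=500, distribution="fixed")
        )
        assert bundle.matrix.sum() == 500
        assert truth["n_transcripts"].sum() == 500
        # all counts land on the human gene block
        human_cols = bundle.genes["species"] == "human"
        assert bundle.matrix[:, np.nonzero(human_cols.to_numpy())[0]].sum() == 500

    def test_transcript_conservation_with_ambient(self):
        layout, _ = torus_layout(300, 300, 0.5, seed=7)
        cap = CaptureConfig(r_e=60.0, ambient_fraction=0.4, seed=3)
        bundle, truth = simulate_experiment(layout, cap, PROFILES, TranscriptModel(mean=200))
        direct = truth["n_transcripts"].sum()
        total = bundle.matrix.sum()
        ambient = total - direct
        assert ambient >= 0
        # per-bead ambient is round(f/(1-f) * direct): matches within rounding
        assert ambient == pytest.approx(direct * 0.4 / 0.6, rel=0.02)

    def test_torus_multiplet_matches_closed_form(self):
        lam = 0.3
        layout, side = torus_layout(8000, 8000, lam, seed=8)
        cap = CaptureConfig(r_e=60.0, seed=4)
        bundle, truth = simulate_experiment(layout, cap, PROFILES, TranscriptModel(mean=50))
        stats_ = empirical_stats(truth, n_cells_input=8000, n_beads=8000)
        rho = 8000 / side**2
        metrics = design_metrics(DesignParams(rho_b=rho, rho_c=rho, r_e=60.0))
        for observed, expected, n in [
            (stats_["bead_yield"], metrics.bead_yield, 8000),
            (stats_["cell_yield"], metrics.cell_yield, 8000),
            (
                stats_["multiplet_fraction"],
                metrics.multiplet_barcoded,
                int(round(8000 * metrics.bead_yield)),
            ),
        ]:
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se

    def test_hard_boundary_yields_not_above_torus(self):
        """Same positions, only the metric changes: torus adds wrap-around
        neighbours, so hard-boundary yields can never exceed torus yields."""
        layout_t, side = torus_layout(600, 600, 0.4, r_e=100.0, seed=9)
        layout_h = Layout(
            width=layout_t.width, height=layout_t.height,
            bead_xy=layout_t.bead_xy, cell_xy=layout_t.cell_xy,
            cell_species=layout_t.cell_species, boundary="hard",
        )
        cap = CaptureConfig(r_e=100.0, seed=5)
        _, truth_t = simulate_experiment(layout_t, cap, PROFILES, TranscriptModel(mean=20))
        _, truth_h = simulate_experiment(layout_h, cap, PROFILES, TranscriptModel(mean=20))
        st_t = empirical_stats(truth_t, 600, 600)
        st_h = empirical_stats(truth_h, 600, 600)
        assert st_h["cell_yield"] <= st_t["cell_yield"]
        assert st_h["bead_yield"] <= st_t["bead_yield"]

    def test_gaussian_kernel_prefers_near_beads(self):
        layout = Layout(
            width=500.0, height=500.0,
            bead_xy=np.array([[100.0, 100.0], [150.0, 100.0]]),
            cell_xy=np.array([[110.0, 100.0]]),
            cell_species=np.array(["human"], dtype=object),
        )
        cap = CaptureConfig(r_e=60.0, kernel="gaussian", seed=6)
        bundle, _ = simulate_experiment(
            layout, cap, PROFILES, TranscriptModel(mean=2000, distribution="fixed")
        )
        totals = bundle.totals_per_barcode()
        assert totals[0] > totals[1]  # 10 um away beats 40 um away

    def test_missing_profile_rejected(self):
        layout, _ = torus_layout(10, 10, 0.3, seed=10)
        with pytest.raises(ValueError, match="no profile"):
            simulate_experiment(layout, CaptureConfig(r_e=60.0, seed=1), PROFILES[:1])


class TestEmpiricalStats:
    def test_empty_truth_warns_zeros(self):
        import pandas as pd

        empty = pd.DataFrame(columns=["bead_index", "cell_index", "distance", "n_transcripts"])
        with pytest.warns(UserWarning):
            out = empirical_stats(empty, 100, 100)
        assert out == {"cell_yield": 0.0, "multiplet_fraction": 0.0, "bead_yield": 0.0}

    def test_cell_yield_invariant_to_cell_density(self):
        """Doubling cell density at fixed bead density leaves cell yield
        unchanged within sampling error."""
        r_e = 60.0
        side = math.sqrt(4000 * math.pi * r_e**2 / 0.8)  # lambda_b = 0.8
        yields = []
        for n_cells, seed in ((2000, 21), (4000, 22)):
            layout = make_layout(4000, n_cells, side, side,
                                 {"human": 0.5, "mouse": 0.5}, boundary="torus", seed=seed)
            _, truth = simulate_experiment(
                layout, CaptureConfig(r_e=r_e, seed=seed), PROFILES, TranscriptModel(mean=20)
            )
            yields.append(empirical_stats(truth, n_cells, 4000)["cell_yield"])
        p = 1.0 - math.exp(-0.8)
        se = math.sqrt(p * (1 - p) * (1 / 2000 + 1 / 4000))
        assert abs(yields[0] - yields[1]) < 3 * se
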