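"""Monte-Carlo realization of the transient-reaction-chamber picture.

Beads and cells are placed uniformly at random on a 2-D region.  Each cell,
once lysed, is captured by the beads within the effective capture radius
``r_e`` (sharp "uniform" kernel, matching the Poisson algebra of
:mod:`onepotseq.design`, or a Gaussian kernel with σ = r_e/2 reflecting the
diffusion profile).  A cell's captured transcripts are split multinomially
between its capturing beads by kernel weight; gene identities are drawn
from per-species expression profiles; an optional ambient component draws
from the pooled all-cell profile.  The truth table records exactly which
cells contribute to each bead, so empirical capture statistics can be
compared with the closed forms.

The torus boundary reproduces the Poisson model exactly and is used for
oracle tests; the hard boundary is the realistic default (edge beads see
fewer cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .io import MatrixBundle
from .synth import SpeciesProfile

__all__ = [
    "Layout",
    "CaptureConfig",
    "TranscriptModel",
    "place_uniform",
    "make_layout",
    "simulate_experiment",
    "empirical_stats",
]


@dataclass
class Layout:
    """Planar positions of beads and cells, with species labels per cell."""

    width: float
    height: float
    bead_xy: np.ndarray
    cell_xy: np.ndarray
    cell_species: np.ndarray
    boundary: str = "hard"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("region dimensions must be > 0")
        if self.boundary not in ("hard", "torus"):
            raise ValueError(f"boundary must be 'hard' or 'torus', got {self.boundary!r}")
        self.bead_xy = np.asarray(self.bead_xy, dtype=float).reshape(-1, 2)
        self.cell_xy = np.asarray(self.cell_xy, dtype=float).reshape(-1, 2)
        self.cell_species = np.asarray(self.cell_species, dtype=object)
        if len(self.cell_species) != len(self.cell_xy):
            raise ValueError("one species label is required per cell")
        for name, xy in (("bead", self.bead_xy), ("cell", self.cell_xy)):
            if len(xy) and (
                xy.min(initial=0.0) < 0
                or xy[:, 0].max(initial=0.0) >= self.width
                or xy[:, 1].max(initial=0.0) >= self.height
            ):
                raise ValueError(f"{name} coordinates outside [0,width) x [0,height)")

    @property
    def n_beads(self) -> int:
        return len(self.bead_xy)

    @property
    def n_cells(self) -> int:
        return len(self.cell_xy)


@dataclass(frozen=True)
class CaptureConfig:
    """How beads capture transcripts from nearby lysed cells."""

    r_e: float
    kernel: str = "uniform"
    capture_efficiency: float = 1.0
    ambient_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.r_e < 0:
            raise ValueError("r_e must be >= 0")
        if self.kernel not in ("uniform", "gaussian"):
            raise ValueError(f"kernel must be 'uniform' or 'gaussian', got {self.kernel!r}")
        if not 0.0 <= self.capture_efficiency <= 1.0:
            raise ValueError("capture_efficiency must be in [0, 1]")
        if not 0.0 <= self.ambient_fraction < 1.0:
            raise ValueError("ambient_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TranscriptModel:
    """Distribution of total transcripts per cell.

    "lognormal" uses the given mean and coefficient of variation;
    "fixed" gives every cell exactly ``mean`` transcripts.
    """

    mean: float = 2000.0
    cv: float = 0.3
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.distribution not in ("lognormal", "fixed"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "fixed" or self.cv == 0:
            return np.full(n, int(round(self.mean)), dtype=np.int64)
        sigma2 = math.log(1.0 + self.cv**2)
        mu = math.log(self.mean) - sigma2 / 2.0
        draws = rng.lognormal(mu, math.sqrt(sigma2), size=n)
        return np.maximum(np.rint(draws).astype(np.int64), 0)


def place_uniform(
    n: int, width: float, height: float, seed: int | None = None
) -> np.ndarray:
    """n i.i.d. uniform points on [0, width) × [0, height)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if width <= 0 or height <= 0:
        raise ValueError("region dimensions must be > 0")
    rng = np.random.default_rng(seed)
    xy = rng.random((n, 2))
    xy[:, 0] *= width
    xy[:, 1] *= height
    return xy


def make_layout(
    n_beads: int,
    n_cells: int,
    width: float,
    height: float,
    species_fractions: dict[str, float] | None = None,
    boundary: str = "hard",
    seed: int | None = None,
) -> Layout:
    """Uniformly random layout with cells assigned species by the given mix."""
    rng = np.random.default_rng(seed)
    bead_xy = place_uniform(n_beads, width, height, seed=rng.integers(2**31))
    cell_xy = place_uniform(n_cells, width, height, seed=rng.integers(2**31))
    if species_fractions is None:
        species_fractions = {"A": 0.5, "B": 0.5}
    labels = np.array(list(species_fractions), dtype=object)
    probs = np.array([species_fractions[s] for s in labels], dtype=float)
    probs = probs / probs.sum()
    species = labels[rng.choice(len(labels), size=n_cells, p=probs)]
    return Layout(
        width=width,
        height=height,
        bead_xy=bead_xy,
        cell_xy=cell_xy,
        cell_species=species,
        boundary=boundary,
    )


def _neighbor_pairs(layout: Layout, r_e: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(bead_idx, cell_idx, distance) for every cell within r_e of a bead."""
    if layout.n_beads == 0 or layout.n_cells == 0 or r_e == 0.0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, float))
    if layout.boundary == "torus":
        if r_e > min(layout.width, layout.height) / 2:
            raise ValueError("torus mode requires r_e <= min(width, height)/2")
        tree = cKDTree(layout.cell_xy, boxsize=(layout.width, layout.height))
    else:
        tree = cKDTree(layout.cell_xy)
    neighbors = tree.query_ball_point(layout.bead_xy, r_e)
    beads, cells = [], []
    for b, idx in enumerate(neighbors):
        beads.extend([b] * len(idx))
        cells.extend(idx)
    beads = np.asarray(beads, dtype=int)
    cells = np.asarray(cells, dtype=int)
    diff = np.abs(layout.bead_xy[beads] - layout.cell_xy[cells])
    if layout.boundary == "torus":
        diff = np.minimum(diff, np.array([layout.width, layout.height]) - diff)
    dist = np.hypot(diff[:, 0], diff[:, 1])
    return beads, cells, dist


def simulate_experiment(
    layout: Layout,
    capture: CaptureConfig,
    profiles: list[SpeciesProfile],
    mrna_per_cell: TranscriptModel | None = None,
) -> tuple[MatrixBundle, pd.DataFrame]:
    """Run one capture experiment and return (count matrix, truth table).

    The truth table has one row per (bead, contributing cell) pair with the
    bead id, cell index, species, distance and the number of transcripts the
    bead received from that cell.  Bit-identical output for identical layout,
    config and seed.
    """
    if not profiles:
        raise ValueError("at least one species profile is required")
    if mrna_per_cell is None:
        mrna_per_cell = TranscriptModel()
    by_species = {p.species: p for p in profiles}
    missing = set(layout.cell_species) - set(by_species)
    if missing:
        raise ValueError(f"no profile for species: {sorted(missing)}")

    rng = np.random.default_rng(capture.seed)
    gene_table = pd.concat(
        [
            pd.DataFrame({"gene": p.gene_ids, "species": p.species})
            for p in profiles
        ],
        ignore_index=True,
    )
    gene_offset = {}
    off = 0
    for p in profiles:
        gene_offset[p.species] = off
        off += len(p.gene_ids)
    n_genes = off

    beads, cells, dist = _neighbor_pairs(layout, capture.r_e)
    if capture.kernel == "gaussian":
        sigma = capture.r_e / 2.0
        weights = np.exp(-(dist**2) / (2.0 * sigma**2))
    else:
        weights = np.ones_like(dist)

    totals = mrna_per_cell.sample(layout.n_cells, rng)
    captured = rng.binomial(totals, capture.capture_efficiency)

    # per-cell multinomial split of captured transcripts across its beads
    order = np.argsort(cells, kind="stable")
    beads_o, cells_o, w_o, dist_o = beads[order], cells[order], weights[order], dist[order]
    bounds = np.searchsorted(cells_o, np.arange(layout.n_cells + 1))
    truth_rows: list[tuple[int, int, float, int]] = []  # bead, cell, dist, n
    mat_rows: list[int] = []
    mat_cols: list[int] = []
    mat_vals: list[int] = []

    # pooled ambient profile: every cell contributes its species profile
    species_counts = pd.Series(layout.cell_species).value_counts()
    ambient = np.zeros(n_genes)
    for sp, cnt in species_counts.items():
        p = by_species[sp]
        o = gene_offset[sp]
        ambient[o : o + len(p.gene_ids)] += cnt * p.mean_expression
    if ambient.sum() > 0:
        ambient = ambient / ambient.sum()

    for c in range(layout.n_cells):
        lo, hi = bounds[c], bounds[c + 1]
        if lo == hi:
            continue
        n_cap = int(captured[c])
        b_idx, w, d = beads_o[lo:hi], w_o[lo:hi], dist_o[lo:hi]
        alloc = rng.multinomial(n_cap, w / w.sum()) if n_cap > 0 else np.zeros(len(w), int)
        sp = layout.cell_species[c]
        prof = by_species[sp]
        o = gene_offset[sp]
        for b, n_alloc, dd in zip(b_idx, alloc, d):
            truth_rows.append((int(b), c, float(dd), int(n_alloc)))
            if n_alloc > 0:
                gene_draw = rng.multinomial(int(n_alloc), prof.mean_expression)
                nz = np.nonzero(gene_draw)[0]
                mat_rows.extend([int(b)] * len(nz))
                mat_cols.extend((o + nz).tolist())
                mat_vals.extend(gene_draw[nz].tolist())

    matrix = sparse.csr_matrix(
        sparse.coo_matrix(
            (mat_vals, (mat_rows, mat_cols)),
            shape=(layout.n_beads, n_genes),
            dtype=np.int64,
        )
    )
    if capture.ambient_fraction > 0 and ambient.sum() > 0:
        f = capture.ambient_fraction
        nonamb = np.asarray(matrix.sum(axis=1)).ravel()
        n_amb = np.rint(nonamb * f / (1.0 - f)).astype(np.int64)
        amb_rows = []
        for b in np.nonzero(n_amb)[0]:
            draw = rng.multinomial(int(n_amb[b]), ambient)
            nz = np.nonzero(draw)[0]
            for j in nz:
                amb_rows.append((b, j, draw[j]))
        if amb_rows:
            bb, jj, vv = zip(*amb_rows)
            matrix = matrix + sparse.coo_matrix(
                (vv, (bb, jj)), shape=matrix.shape, dtype=np.int64
            )

    barcodes = np.array([f"BEAD{i:06d}" for i in range(layout.n_beads)], dtype=object)
    bundle = MatrixBundle(matrix=matrix, barcodes=barcodes, genes=gene_table)
    truth = pd.DataFrame(
        truth_rows, columns=["bead_index", "cell_index", "distance", "n_transcripts"]
    )
    if len(truth):
        truth["bead"] = barcodes[truth["bead_index"].to_numpy()]
        truth["species"] = layout.cell_species[truth["cell_index"].to_numpy()]
    else:
        truth["bead"] = pd.Series(dtype=object)
        truth["species"] = pd.Series(dtype=object)
    return bundle, truth


def empirical_stats(
    truth: pd.DataFrame, n_cells_input: int, n_beads: int
) -> dict[str, float]:
    """Capture statistics from a simulation truth table.

    cell_yield = distinct cells reached by ≥1 bead / input cells;
    multiplet_fraction = beads with ≥2 contributing cells / beads with ≥1;
    bead_yield = beads with ≥1 contributing cell / all beads.
    """
    if n_cells_input <= 0:
        raise ValueError("n_cells_input must be > 0")
    if n_beads <= 0:
        raise ValueError("n_beads must be > 0")
    if len(truth) == 0:
        import warnings

        warnings.warn("empty truth table: all statistics are zero", stacklevel=2)
        return {"cell_yield": 0.0, "multiplet_fraction": 0.0, "bead_yield": 0.0}
    cells_per_bead = truth.groupby("bead_index")["cell_index"].nunique()
    n_occupied = len(cells_per_bead)
    n_multi = int((cells_per_bead >= 2).sum())
    n_cells_captured = truth["cell_index"].nunique()
    return {
        "cell_yield": n_cells_captured / n_cells_input,
        "multiplet_fraction": n_multi / n_occupied if n_occupied else 0.0,
        "bead_yield": n_occupied / n_beads,
    }
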