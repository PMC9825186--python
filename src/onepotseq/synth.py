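"""Synthetic inputs for the pipeline: species expression profiles, barcode
whitelists, error-bearing read records, perturbation matrices and saturation
series.

Every generator takes a seed and is fully deterministic given it, and every
output carries its ground truth (true barcode/UMI columns, responding-cell
lists) so downstream modules can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MatrixBundle

__all__ = [
    "SpeciesProfile",
    "PerturbationSpec",
    "gen_profiles",
    "gen_whitelist",
    "gen_reads",
    "gen_perturbation",
    "gen_saturation_series",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SpeciesProfile:
    """Relative gene abundances for one species.

    Gene identifiers are prefixed with the species label so that profiles of
    distinct species have disjoint gene sets.
    """

    species: str
    gene_ids: np.ndarray
    mean_expression: np.ndarray

    def __post_init__(self) -> None:
        genes = np.asarray(self.gene_ids, dtype=object)
        expr = np.asarray(self.mean_expression, dtype=float)
        if genes.shape != expr.shape or genes.ndim != 1:
            raise ValueError("gene_ids and mean_expression must be matching 1-D arrays")
        if np.any(expr < 0):
            raise ValueError("abundances must be non-negative")
        total = expr.sum()
        if total <= 0:
            raise ValueError("profile must have positive total abundance")
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "mean_expression", expr / total)


@dataclass(frozen=True)
class PerturbationSpec:
    """A known expression shift on defined gene lists.

    effect_size is the shift in log-expression units applied to responding
    cells: induced genes get +effect_size, suppressed genes −effect_size.
    """

    induced_genes: tuple[str, ...]
    suppressed_genes: tuple[str, ...]
    effect_size: float
    fraction_cells_responding: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "induced_genes", tuple(self.induced_genes))
        object.__setattr__(self, "suppressed_genes", tuple(self.suppressed_genes))
        if set(self.induced_genes) & set(self.suppressed_genes):
            raise ValueError("induced and suppressed gene lists must be disjoint")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.fraction_cells_responding <= 1.0:
            raise ValueError("fraction_cells_responding must be in [0, 1]")


def gen_profiles(
    n_genes_per_species: int,
    n_species: int = 2,
    dispersion: float = 1.0,
    seed: int | None = None,
    species_names: list[str] | None = None,
) -> list[SpeciesProfile]:
    """Log-normal relative abundances for each species, disjoint gene sets.

    ``dispersion`` is the SD of log-abundance; 0 gives uniform profiles.
    """
    if n_genes_per_species <= 0:
        raise ValueError("n_genes_per_species must be > 0")
    if n_species <= 0:
        raise ValueError("n_species must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if species_names is None:
        species_names = [chr(ord("A") + i) for i in range(n_species)]
    if len(species_names) != n_species or len(set(species_names)) != n_species:
        raise ValueError("species_names must be n_species distinct labels")
    rng = np.random.default_rng(seed)
    profiles = []
    for name in species_names:
        genes = np.array(
            [f"{name}_g{i:05d}" for i in range(n_genes_per_species)], dtype=object
        )
        abundance = np.exp(dispersion * rng.standard_normal(n_genes_per_species))
        profiles.append(SpeciesProfile(species=name, gene_ids=genes, mean_expression=abundance))
    return profiles


def _hamming_matrix(codes: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    return (codes != candidate[None, :]).sum(axis=1)


def gen_whitelist(
    n: int,
    length: int = 12,
    min_distance: int = 3,
    seed: int | None = None,
    max_tries: int = 100_000,
) -> list[str]:
    """Random barcodes with guaranteed minimum pairwise Hamming distance.

    Rejection sampling; with distance ≥ 3, single-base errors cannot turn
    one whitelist barcode into a neighbour of another, so Hamming-1 collapse
    is unambiguous.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    accepted = np.empty((0, length), dtype="<U1")
    tries = 0
    while len(accepted) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} barcodes at min distance {min_distance}"
            )
        cand = BASES[rng.integers(0, 4, size=length)]
        if len(accepted) == 0 or _hamming_matrix(accepted, cand).min() >= min_distance:
            accepted = np.vstack([accepted, cand])
    return ["".join(row) for row in accepted]


def _random_kmers(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    arr = BASES[rng.integers(0, 4, size=(n, length))]
    return np.array(["".join(row) for row in arr], dtype=object)


def _distinct_umis(rng: np.random.Generator, n: int, length: int = 8) -> list[str]:
    """Draw n UMIs at pairwise Hamming distance >= 2.

    Within one (barcode, gene) group, molecules one substitution apart are
    indistinguishable from sequencing errors and would be merged by any
    single-base-tolerant deduplication; keeping them >= 2 apart makes the
    generated matrix exact ground truth for error-free reads.
    """
    accepted: list[str] = []
    arr = np.empty((n, length), dtype="<U1")
    count = 0
    while count < n:
        cand = BASES[rng.integers(0, 4, size=length)]
        if count == 0 or (arr[:count] != cand[None, :]).sum(axis=1).min() >= 2:
            arr[count] = cand
            accepted.append("".join(cand))
            count += 1
    return accepted


def _substitute(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _indel(seq: str, rng: np.random.Generator, fixed_length: bool) -> str:
    """Apply one insertion or deletion; re-truncate/pad when fixed_length."""
    L = len(seq)
    if rng.random() < 0.5:  # deletion
        p = int(rng.integers(0, L))
        out = seq[:p] + seq[p + 1 :]
        if fixed_length:
            out += BASES[rng.integers(0, 4)]
    else:  # insertion
        p = int(rng.integers(0, L + 1))
        base = BASES[rng.integers(0, 4)]
        out = seq[:p] + base + seq[p:]
        if fixed_length:
            out = out[:L]
    return out


def gen_reads(
    umi_counts: MatrixBundle,
    substitution_rate: float = 0.0,
    indel_rate: float = 0.0,
    whitelist: list[str] | None = None,
    seed: int | None = None,
    mean_reads_per_umi: float = 3.0,
    umi_length: int = 8,
    fixed_length: bool = True,
) -> pd.DataFrame:
    """Expand a UMI count matrix into error-bearing read records.

    Each nonzero entry (barcode, gene) with u UMIs produces u distinct
    molecules; each molecule is sequenced 1 + Poisson(mean_reads_per_umi − 1)
    times.  Per read, every barcode/UMI base is substituted independently
    with ``substitution_rate`` and the barcode suffers a single indel with
    ``indel_rate`` (re-padded/truncated to the sequencing length when
    ``fixed_length``).  Ground-truth columns are always emitted; corruption
    never creates or drops reads.
    """
    if not 0.0 <= substitution_rate < 1.0 or not 0.0 <= indel_rate < 1.0:
        raise ValueError("error rates must lie in [0, 1)")
    if substitution_rate + indel_rate >= 1.0:
        raise ValueError("combined per-read error rates must be < 1")
    if mean_reads_per_umi < 1.0:
        raise ValueError("mean_reads_per_umi must be >= 1")
    rng = np.random.default_rng(seed)
    n_bc = len(umi_counts.barcodes)
    if whitelist is not None:
        if len(whitelist) < n_bc:
            raise ValueError(
                f"whitelist has {len(whitelist)} barcodes but the matrix has {n_bc}"
            )
        barcode_seq = {bc: whitelist[i] for i, bc in enumerate(umi_counts.barcodes)}
    else:
        barcode_seq = {bc: bc for bc in umi_counts.barcodes}
        for bc in umi_counts.barcodes:
            if set(bc) - set("ACGT"):
                raise ValueError(
                    "matrix barcodes are not ACGT sequences; pass a whitelist"
                )

    genes = umi_counts.genes["gene"].to_numpy(dtype=object)
    coo = umi_counts.matrix.tocoo()
    rows: list[tuple[str, str, str, str, str]] = []
    for i, j, u in zip(coo.row, coo.col, coo.data):
        true_bc = barcode_seq[umi_counts.barcodes[i]]
        gene = genes[j]
        umis = _distinct_umis(rng, int(u), umi_length)
        mults = 1 + rng.poisson(mean_reads_per_umi - 1.0, size=int(u))
        for umi, m in zip(umis, mults):
            for _ in range(int(m)):
                obs_bc = _substitute(true_bc, rng, substitution_rate)
                if indel_rate > 0 and rng.random() < indel_rate:
                    obs_bc = _indel(obs_bc, rng, fixed_length)
                obs_umi = _substitute(umi, rng, substitution_rate)
                rows.append((obs_bc, obs_umi, gene, true_bc, umi))
    return pd.DataFrame(
        rows, columns=["cell_barcode", "umi", "gene", "true_barcode", "true_umi"]
    )


def gen_perturbation(
    control: MatrixBundle,
    spec: PerturbationSpec,
    seed: int | None = None,
) -> tuple[MatrixBundle, np.ndarray]:
    """Apply a known log-space shift to listed genes in responding cells.

    Each affected entry is re-sampled as Poisson(count · exp(±effect_size));
    all other entries are copied unchanged.  Returns the perturbed bundle and
    the boolean responding-cell mask (ground truth).
    """
    gene_index = {g: i for i, g in enumerate(control.genes["gene"])}
    unknown = [
        g
        for g in (*spec.induced_genes, *spec.suppressed_genes)
        if g not in gene_index
    ]
    if unknown:
        raise ValueError(f"genes not present in the matrix: {unknown}")
    rng = np.random.default_rng(seed)
    n_cells = len(control.barcodes)
    responding = rng.random(n_cells) < spec.fraction_cells_responding
    dense = control.to_dense().astype(float)
    for genes, sign in ((spec.induced_genes, 1.0), (spec.suppressed_genes, -1.0)):
        if not genes:
            continue
        cols = [gene_index[g] for g in genes]
        block = dense[np.ix_(responding, cols)]
        dense[np.ix_(responding, cols)] = rng.poisson(
            block * math.exp(sign * spec.effect_size)
        )
    out = MatrixBundle(
        matrix=dense.astype(np.int64),
        barcodes=control.barcodes.copy(),
        genes=control.genes.copy(),
    )
    return out, responding


def gen_saturation_series(
    a: float,
    b: float,
    x0: float,
    depths,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean-UMI-versus-depth points from the curve y = a + b/(x + x0).

    Gaussian noise of the stated SD is added to each y.
    """
    depths = np.asarray(depths, dtype=float)
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")
    if np.any(depths + x0 == 0):
        raise ValueError("x + x0 must be nonzero for every depth")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = a + b / (depths + x0)
    if np.any(y < 0):
        raise ValueError("curve is negative over the requested depths")
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(depths))
    return pd.DataFrame({"depth": depths, "mean_umi": y})
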