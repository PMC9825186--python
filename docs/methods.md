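# Methods

This note documents the models implemented in `onepotseq`, the defaults and
the reasoning behind them, the numerical choices, what the synthetic data
do and do not emulate, and known limitations.

## Units

Fixed package-wide: micrometres (length), seconds (time), micromolar
(concentration), nanolitres for droplet volumes (1 nl = 10⁶ μm³). Surface
densities are per μm²; `rho_from_count` converts cells-per-well using
plate-format growth areas (12-well = 3.8 cm², an industry-typical value —
configurable when a different plate is used).

## Diffusion model

A lysed cell is a sphere of radius R with uniform internal mRNA
concentration c₀; transcripts then diffuse freely with coefficient D. The
radial profile is the classic image-source integral over the initial
sphere. Defaults: D = 1.0 μm²/s (literature estimates for mRNA-sized
nucleic acids in water/cytosol), R = 5 μm, c₀ = 1.2 μM. Note that all
*fractional* quantities (cumulative fraction, diffusion distance, the
droplet ratio) are independent of c₀; it only scales absolute
concentrations.

Numerics:

- The ξ-integrand is evaluated as
  `ξ·exp(−(r−ξ)²/4Dt)·(−expm1(−ξr/Dt))`, algebraically identical to the
  difference of Gaussians but free of both overflow (large ξr/Dt) and
  cancellation (small r). `scipy.integrate.quad` with
  epsabs 1e-12 / epsrel 1e-10; for 0 < r < R the quadrature is given a
  breakpoint at ξ = r, where early-time profiles have a sharp spike.
- r = 0 is evaluated at an offset of 1e-6 μm; the expm1 form is smooth
  there, so the offset only avoids the literal 1/r.
- t = 0 returns the exact initial condition rather than a quadrature.
- The cumulative fraction is the shell integral ∫₀ʳ 4πs²c(s,t) ds
  normalised by c₀·(4/3)πR³, again by adaptive quadrature; the diffusion
  distance solves cumulative = fraction by Brent's method on
  [10⁻⁴, 10⁴] μm with xtol 1e-10.
- Everything depends on D and t only through the product D·t; the test
  suite checks this, plus mass conservation (≤ 10⁻³ relative across
  t = 1…900 s), agreement with the independent erf closed form of the same
  integral, a 10⁶-particle random-walk Monte Carlo, and the Maxwell radial
  CDF in the point-source limit R → 0 (90th percentile at 2.5003·√(2Dt)).

With the defaults, the 90%-mass radius at t = 300 s computes to 61.5 μm,
and the mean concentration within 40 μm is ≈ 2.05× the 1 nl-droplet
dilution of the same transcripts.

## Poisson loading model

Occupancy of a chamber of effective radius r_e is Poisson with
λ = ρπr_e². The four derived probabilities (cell yield, bead yield,
multiplet among all beads, multiplet among barcoded beads) are evaluated
with `expm1` so the λ → 0 limits are exact (multiplet-among-barcoded → λ/2);
λ = 0 returns the limit 0 analytically rather than 0/0.

`fit_effective_radius` maximises the binomial likelihood of observed
multiplet counts among barcoded beads across cell densities; the likelihood
is optimised on log r_e (bounded Brent), and the standard error comes from
the observed information by central difference. Weighted least squares on
proportions is available as an option; the likelihood default behaves
correctly at low counts. All-zero multiplet counts leave r_e unidentified
from below and return the lower search bound with a flag; a single density
is fit but flagged as weakly identified. The barcoded-bead multiplet
formula is the default fitting target because sequencing only observes
barcoded beads.

## Spatial simulator

Beads and cells are placed i.i.d. uniformly on a rectangle. Neighbour
search uses a k-d tree; the torus boundary (periodic box) realises the
Poisson model exactly and is used for oracle tests, while the hard
boundary is the realistic default (edge chambers are truncated, so hard
yields are never above torus yields — with shared positions the torus
capture set is a superset, which the tests exploit).

Capture: a cell's transcript total is log-normal (default mean 2000,
CV 0.3; the count distribution is a modelling choice, not a measured one),
a binomial `capture_efficiency` fraction of it is captured, and that mass
is split multinomially among the beads within r_e — equally for the
"uniform" kernel (the sharp radius implicit in the Poisson algebra) or by
exp(−d²/2σ²), σ = r_e/2, for the "gaussian" kernel that mimics the
diffusion profile. How a multi-bead cell's transcripts divide between
beads is an assumption (multinomial by kernel weight); no measurement
constrains it. Gene identities are multinomial draws from per-species
profiles. Ambient transcripts are drawn from the pooled all-cell profile
and allocated per bead in proportion to its non-ambient total
(`f/(1−f)` × direct counts), so empty beads stay near-empty and the knee
curve fattens the way contaminated libraries do.

A multiplet is defined at the bead: ≥ 2 cells within r_e of it, recorded
in the truth table regardless of how many transcripts were actually
allocated. Note the distinction between two multiplet readouts: the
truth-table (geometric) multiplet fraction matches the closed form
1 − λe^(−λ)/(1 − e^(−λ)), while the *observable* mixed-species rate in a
50/50 barnyard experiment is (1 − e^(−λ/2))²/(1 − e^(−λ)) — roughly half,
because same-species doublets look pure. Both are tested against their
own closed forms.

## Synthetic data

Generators are seed-deterministic and always emit ground truth. Species
profiles are log-normal relative abundances with disjoint, species-prefixed
gene identifiers. Barcode whitelists are rejection-sampled to pairwise
Hamming distance ≥ 3, so a single error cannot bridge two true barcodes.
Ground-truth UMIs within one (barcode, gene) group are drawn at pairwise
distance ≥ 2: molecules one substitution apart are indistinguishable from
sequencing errors by construction, and any single-base-tolerant
deduplication would merge them, so keeping them apart is what makes the
error-free round trip exact.

Reads: each molecule is sequenced 1 + Poisson(mean − 1) times (default
mean 3 reads/UMI). Per read, every barcode and UMI base substitutes
independently at the stated rate; the barcode additionally suffers a
single insertion or deletion at the indel rate. By default indels are
re-truncated/padded to the fixed 12 bp sequencing length (what a
fixed-position barcode extractor would produce); `fixed_length=False`
emits 11/13 bp barcodes instead. Corruption never creates or drops reads.

Perturbations shift the listed genes of responding cells by ±effect_size
in log space and re-sample the affected entries as Poisson; unlisted
entries are copied unchanged. What the synthetic data do **not** emulate:
base-quality structure, alignment ambiguity, species-chimeric reads,
gene-length or GC bias, cell-cycle or batch structure. Tests passing on
these data show the algorithms are correct under the stated error model,
not that real libraries meet that model.

## Barcode/UMI collapse

Directional rule: observed barcode b merges into neighbour a iff
dist(a, b) ≤ 1 and count(a) ≥ 2·count(b) − 1, walking outward (BFS) from
the highest-count nodes so that chains of errors are absorbed; ties break
lexicographically for determinism, and a "greater" mode (strict
count(a) > count(b)) is available for comparison. Neighbourhood includes
Hamming-1 substitutions, true single indels for length-±1 pairs, and
indel-with-repad pairs at the fixed length (b[:−1] a deletion of a, or
vice versa). Candidates are bucketed by single-deletion signatures and
verified exactly, so collapse is near-linear in practice. UMIs use the
same rule, substitution-only by default (indel provisions attach to the
barcode). Read counts are conserved exactly and the result is independent
of input order. Collapse is de novo; a whitelist is not consulted.

## Saturation

Subsampling thins each molecule's read multiplicity binomially (keeping
each read independently with probability f), which matches subsampling
aligned reads; a molecule with multiplicity m survives with
1 − (1−f)^m. The cell set is the barcodes with > 500 distinct UMIs at
full depth and is frozen across fractions (a `refit_cells` toggle
re-selects per depth). The fit of y = a + b/(x + x₀) uses
Levenberg–Marquardt with tolerances 1e-14, initialised at
a₀ = 1.05·max(y), x₀₀ = median(x), and b₀ solved from the first point; a
constant series short-circuits to a = y, b = 0 with a degenerate flag, and
fits whose curve goes negative over the data range are flagged. x₀ is the
curve's depth offset (often written c; renamed to avoid colliding with the
concentration symbol).

## Signature scores and composition

"Normalised expression" is interpreted as the per-gene z-score of
log(1 + count) across cells (natural log, pseudocount 1 — the standard
reading; min–max normalisation is exposed as an option). Genes with mean
log count < 0.1 are filtered first; zero-variance genes cannot be
standardised and are excluded with a warning. A cell's induced (or
suppressed) score is the mean z over the surviving genes of that list.
Real induced/suppressed gene lists are user-supplied; tests use synthetic
lists with known shifts. Reference matching is plain Pearson correlation
on the intersected gene set (≥ 3 genes). Enrichment folds divide sample
cell-type fractions by a baseline composition; a type absent from the
baseline but present in the sample is infinite enrichment and is excluded
from the numeric output with a warning.

## Problem sizes used in the test suite

Oracle comparisons run at sizes where binomial error bars are tight but
the suite stays quick: 20,000 beads/cells per torus condition for the
closed-form checks (3 loadings), 10,000 beads per density × 5 densities ×
20 replicates for radius recovery, 10⁵ reads for collapse fidelity, 100
replicates for the noisy saturation fit, and 10⁶ particles for the
random-walk diffusion oracle. These are the package's own choices of
desk-scale study conditions.

## Known limitations

- No convection or detergent-front modelling: lysis-method differences
  (direct vs diffusive) enter only through the fitted effective radius.
- No mRNA degradation or bead-surface capture kinetics; capture is an
  instantaneous geometric event.
- The simulator is 2-D and ignores bead-size exclusion and cell–bead
  adhesion; antibody-assisted capture would appear only as a changed
  effective capture probability.
- Collapse assumes ACGT alphabets and single-error tolerance; it is not a
  general edit-distance clusterer.
- The saturation hyperbola is an empirical fit, not a mechanistic
  complexity model; its asymptote can overshoot the true library
  complexity when the sampled depth range is short.
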