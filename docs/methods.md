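# Methods

This note documents the models behind each module, the defaults that
matter, the numerical choices, and what the synthetic-data generators do and
do not emulate.

## Visual modelling

Cone spectral sensitivities default to template curves from a standard
visual-pigment nomogram (alpha plus beta band) with peak wavelengths
u 370, s 440, m 508, l 560 nm — a UVS-type configuration appropriate for
hummingbirds. Measured curves can be loaded from CSV
(`VisualSystem.from_csv`) and override the templates; the templates are a
stand-in, not a measured hummingbird retina. Sensitivities are normalised to
unit area so that a flat stimulus yields equal relative catches.

The illuminant defaults to flat (ideal). No von Kries normalisation is
applied: quantum catches enter the receptor-noise model as raw integrals,
whose log-ratios are illuminant-invariant under any wavelength-independent
intensity change. Oil-droplet filtering and luminance (double-cone)
contrasts are out of scope.

Receptor noise uses the conventional parameterisation e_i = ω·√(n_ref/n_i)
with ω = 0.1 on the most abundant cone class (l, relative density 4; cone
ratios 1:2:2:4), giving e = (0.2, 0.141, 0.141, 0.1) for (u, s, m, l). The
tetrachromatic ΔS is the standard quadratic form in the log-catch
differences. `noise_scaled_coords` restricts that quadratic form to the
3-D subspace orthogonal to (1,1,1,1) — the intensity direction, where the
form is degenerate — and applies the Cholesky factor of the restricted
metric, so Euclidean distances in the resulting space equal ΔS exactly
(machine precision in practice; asserted to 1e-9).

Group comparisons bootstrap specimens with replacement within each group
(default 1000 replicates, percentile 95% CI) and measure the distance
between *geometric-mean* group catches: the receptor-noise model works on
log catches, where the geometric mean is the natural centroid. A contrast is
flagged discriminable when the CI lower bound exceeds 1 JND.

Hue is the wavelength of maximum reflectance; smoothing is off by default
and ties break to the shortest wavelength, so the statistic is deterministic.

## Optical model

The barbule is modelled as a 1-D stack: air | keratin cortex | top platelet
| (keratin gap | inner platelet) × (n_layers − 1) | semi-infinite keratin.
Each inner platelet is a melanin wall of mel/2, an air core of extent
`air`, and a second mel/2 wall — the measured melanin thickness is read as
the *total* melanin per platelet, split into two walls, because the
reported air diameters exceed the reported melanin thicknesses, so mel
cannot be the whole-platelet thickness.

Air cores are sliced (default 1 nm) and each slice receives the
volume-fraction-weighted arithmetic mean of the air and melanin complex
indices. The lateral air fraction per slice is constant φ for block-shaped
air spaces and parabolic, φ·(1 − (2z′/air)²), for spherical ones. φ
defaults to 1 (lateral packing is not measured). Reflectance comes from the
standard interface/propagation transfer-matrix recursion in the n + ik
convention; unpolarised R is the s/p mean at oblique angles (normal
incidence is the default and matches the closed-form Fresnel and
quarter-wave results to 1e-10; halving the slice size changes R by < 1e-4
on realistic stacks).

Material dispersion is Cauchy n(λ) = A + B/λ² with exponential absorption
k(λ) = k₀·exp(−λ/λ_k); shipped defaults (keratin A = 1.532, B = 5890 nm²;
melanin A = 1.648, B = 23700 nm², k₀ = 0.56, λ_k = 270 nm) are generic
film values and fully configurable, including per-patch melanin.

**Geometry default for the parental/hybrid gorget comparison.** Hummingbird
surficial melanosomes are normally hollow platelets like the deeper layers,
so the qualitative gorget analysis (and the acceptance script) uses the
hollow ("sandwich") top platelet with spherical air spaces. Under that
configuration the simulated parental gorgets both carry a secondary
reflectance peak in the 400–500 nm band that the hybrid's simulation lacks,
with about an order of magnitude between the parental and hybrid peak
prominences. Under the block-air + solid-top alternative the hybrid's main
interference peak throws a strong side-lobe near 415 nm that dominates the
band, so the ordering is geometry-dependent; both geometries remain
available (`air_shape`, `top_platelet_solid`). Peak prominence is measured
relative to the spectral maximum so spectra of different absolute
brightness compare fairly.

## Transgression metrics

Parent-bias is normalised by half the parental separation (a hybrid sitting
exactly on a parent scores 1) and mismatch by the full separation (a score
of 1 means the hybrid is displaced off the transect by one full parental
distance). Centroids are arithmetic means of group rows; colour rows are
computed in the noise-scaled JND coordinates, where squared Euclidean
distance is ΔS². "All sets of traits" is read as all unordered 2-D trait
pairs, the setting in which the two metrics are defined; the per-pair
breakdown is always returned. Raw traits are the default for morphological
tables, with PCA available separately.

## Rates and signal

Contrasts follow the pruning algorithm with the usual branch-length
inflation for ancestral nodes; polytomies are rejected rather than
zero-resolved, because silent resolution changes the contrast count. The
multivariate rate sums squared contrasts over the three colour axes per
node (units: squared Euclidean JND distance per My) and averages over the
n − 1 nodes; the per-axis-mean alternative differs by exactly 3× and is
obtainable by dividing. Its unbiasedness is verified by parameter recovery
on simulated trees (mean over 100 estimates within 5% of truth).

Blomberg's K generalises to multivariate data by summing squared deviations
across axes in both the raw and the tree-covariance-corrected dispersion.
Permutation p-values shuffle tip rows and use the add-one convention with
the observed statistic in the null set; K is undefined (explicit error) for
zero-variance traits. Under Brownian motion the simulated mean K is within
0.1 of 1.

## Hybrid ancestry

Depth and quality thresholds are strict inequalities (a call passes only
with depth > 5 and Q > 20); boundary calls fail. Loci are dropped when any
parental call fails, while focal failures become missing calls. Diagnostic
loci require fixity across all sampled parental individuals — with small
panels this is sample-relative fixity, which inflates the diagnostic set;
the estimator is unbiased given truly fixed differences, which is what the
generator produces.

The CI on h is a binomial profile likelihood (log-likelihood drop of 1.92)
under locus independence; linked loci would make it anticonservative. The
method is recorded in the output. Triangle classification measures distance
to canonical (h, het) points — parentals (0,0), (1,0); F1 (0.5,1);
F2 (0.5,0.5); BC1 (0.25,0.5) and mirrored; BC2 and BC3 halving both
coordinates each backcross generation — and rejects points outside
het ≤ 2·min(h, 1−h) beyond a small tolerance.

## Niche models

The minimum-volume ellipsoid search draws (d+1)-point subsets, takes each
subset's mean/covariance, inflates the candidate to cover ⌈coverage·n⌉
points, and keeps the minimal volume; all subsets are enumerated when their
count is at most max(n_subsets, 5000), otherwise n_subsets (default 500)
random subsets are drawn. A reweighting step then refits the mean and
covariance from the covered points and rescales by the normal-truncation
consistency factor, the standard way to make a robust ellipsoid
commensurate with the underlying covariance. Degenerate subsets are skipped;
an all-singular search errors.

Continuous suitability is s = exp(−D²/2) — a monotone transform of the
Mahalanobis distance that behaves like an unnormalised Gaussian niche
density — and the binary map thresholds D² at the k-th smallest occurrence
distance with k = ⌈0.9·n⌉, which guarantees at least 90% data inclusion on
any input. Schoener's D normalises each surface to sum 1 over the shared
data cells; continuous surfaces are the default for D, binary for maps.

The background similarity test draws |occ| cells uniformly from the data
cells inside the focal species' M polygon, fits a pseudomodel, and compares
it with the other species' true model; p is the add-one proportion of null
D values at least as large as the observed (small p = the observed overlap
exceeds what the accessible background explains, i.e. similarity support).
The identity/equivalency permutation variant (pooled relabelling) is
deliberately not part of the standard outputs. Coordinates are treated as
unprojected degrees; area distortion is ignored at the grid scales used.

Rasters are plain-text ESRI ASCII grids; all layers of a stack share one
grid and no-data mask.

## Synthetic data

The generators are pure functions of their spec (seed included) and
round-trip through the package's writers and readers:

- **Spectra**: sums of Gaussian peaks plus iid Gaussian noise, clipped at 0.
  They emulate peak placement and group separation only — not the angular
  dependence, UV structure or multi-peak shapes of real iridescent plumage.
- **Nanostructure**: traits drawn independently from normals truncated at 0
  around the published per-taxon means, with SD = CI half-width / 1.96
  (the tables report 95% intervals of within-individual variation); layer
  counts round to integers ≥ 1. Trait covariances are not emulated.
- **Crosses**: parental panels fixed for alternative alleles at every locus;
  focal individuals built by Mendelian gamete sampling with free
  recombination (no linkage). Truth records carry *realised* h and het.
  Default panels: 1000 loci, 4 individuals per parental species, DP 30,
  GQ 99, so the depth/quality filters are exercisable.
- **Trees and traits**: Yule trees (pure birth), pendant edges extended by
  one exponential waiting time so the n-th speciation does not leave
  zero-length branches, rescaled to the target depth; traits accrue
  independent Normal(0, σ²·b) increments per axis. Tree-shape realism is
  irrelevant to the estimator tests, which is why a birth–death model is
  not used.
- **Niche systems**: environmental layers are Gaussian random fields
  (white noise smoothed with a σ = 4-cell kernel, standardised);
  occurrences are sampled at cell centres with probability proportional to
  a Gaussian niche density evaluated at the cell environments (default 100
  per species, a typical presence-only sample); M polygons are buffered
  convex hulls of the occurrences. Spatial sampling bias, which motivates
  presence-only ellipsoids in real data, is *not* emulated — so passing
  tests show estimator correctness, not robustness to survey bias.

## Orchestration

A single global seed fans out to per-stage seeds through a fixed counter
scheme, so stages rerun independently and reproduce byte-identical
artefacts; the manifest records each artefact's SHA-256 and seed. Configs
are YAML over a complete default tree; unknown keys are rejected by name.

## Problem sizes

Statistical checks use: 100 trees × 100 tips for rate recovery; 200
replicates of 50-tip trees for the K calibration; 200 replicates of
1000-locus BC1 crosses for ancestry recovery; 100 occurrences per species
and a 60 × 80 grid with 99 background replicates for the niche tests; 1000
bootstrap replicates for colour CIs. These sizes put Monte-Carlo error
comfortably inside the asserted tolerances.

## Known limitations

- The optical model is 1-D: no lateral structure, curvature, disorder or
  angular sweeps (a single configurable incidence angle only), and no
  pigmentary colour. Predicted hues are systematically red-shifted relative
  to measured iridescent spectra, as expected for idealised flat stacks.
- The receptor-noise implementation omits oil-droplet filtering and
  chromatic adaptation.
- Rate estimation assumes homogeneous Brownian motion; no OU/early-burst
  models or clade-specific rates.
- Ancestry estimation assumes unlinked, correctly genotyped diagnostic
  loci; no genomic clines or local ancestry.
- Ellipsoidal niches cannot represent multimodal or strongly skewed niches,
  and the geographic grid is treated as equal-area.
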