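# gorget

Analysis pipeline for asking how hybridization reshapes iridescent plumage
colour — from feather nanostructure, through avian-perceived colour, to
evolutionary rates, genome-wide ancestry and ecological niches. The package
is aimed at evolutionary biologists studying structural colour in birds
(hummingbird gorgets being the motivating system), and ships a synthetic-data
module so that every stage runs and is testable without any external
download.

## What it computes

**Avian colour vision** (`colour_vision`). Reflectance spectra R(λ) on the
bird-visible 300–700 nm band are scored through a UVS-type tetrachromat
visual system: cone quantum catches

    qᵢ = ∫ R(λ) Cᵢ(λ) I(λ) dλ,  i ∈ {u, s, m, l},

tetrahedral colour-space coordinates, and receptor-noise-limited perceptual
distances ΔS in just-noticeable-difference (JND) units, with channel noise
eᵢ = ω·√(n_ref/nᵢ) built from the Weber fraction ω = 0.1 and cone densities
1:2:2:4. A Cholesky factorisation of the receptor-noise metric yields a
perceptually uniform 3-D space in which Euclidean distance equals ΔS, and a
bootstrap over specimens gives group-distance CIs (discriminable when the CI
lower bound exceeds 1 JND).

**Feather optics** (`feather_optics`). Barbule cross-sections — keratin
cortex over stacked hollow melanosome platelets — are discretised into thin
depth slices of uniform effective refractive index and solved with the
transfer-matrix method, giving simulated reflectance spectra and predicted
hue from measured nanostructure (cortex, platelet melanin, air core, keratin
spacing, layer count).

**Transgression metrics** (`trait_divergence`). For a hybrid H against
parental centroids P1, P2 in a 2-D trait plane, with v = P2 − P1 and
midpoint M:

    d_parent-bias = |(H − M)·v̂| / (‖v‖/2),    d_mismatch = ‖(H − M)⊥‖ / ‖v‖,

averaged over all unordered trait pairs: 0 means a perfectly intermediate
hybrid, 1 on the parental transect means "like one parent", and mismatch
above 1 means the hybrid sits farther off the transect than the parents are
apart (transgressive).

**Phylogenetic rates** (`phylo_rate`). Felsenstein's independent contrasts
per colour axis; the multivariate Brownian rate σ² (JND² My⁻¹) as the mean
over nodes of the squared contrast length summed over the three axes;
multivariate Blomberg's K with a tip-permutation test; and the waiting time
T = ΔS²/σ² for a colour divergence to accrue within a lineage.

**Hybrid ancestry** (`hybrid_ancestry`). From a VCF with two parental
panels: depth/quality filtering (strictly > 5× and Q > 20), ancestry-
diagnostic loci (fixed for alternative alleles between panels), hybrid index
h = parent-2 alleles / 2L with a profile-likelihood CI, interspecific
heterozygosity, and nearest-class calls in the (h, het) triangle (parentals
at the corners, F1 at the apex, backcrosses along the sides).

**Niche models** (`niche_model`). Presence-only minimum-volume-ellipsoid
niche models in environmental space; suitability as a transform of
Mahalanobis distance, thresholded at 90% data inclusion; niche overlap by
Schoener's D = 1 − ½Σ|p_A − p_B|; and background similarity tests against
pseudomodels drawn from each species' accessible (M) region.

## Worked example

Simulate gorget reflectance from the published mean nanostructures of the
two parental species and the putative hybrid, and score the hybrid's colour
divergence:

```python
from gorget.feather_optics import (params_from_means,
                                   simulate_feather_spectrum,
                                   secondary_peak_prominence)
from gorget.synthetic_data import nanostructure_means
from gorget.phylo_rate import divergence_time

for taxon in ("branickii", "gularis", "hybrid"):
    p = params_from_means(nanostructure_means(taxon, "gorget")["mean"],
                          air_shape="sphere", top_platelet_solid=False)
    s = simulate_feather_spectrum(p)
    print(taxon, s.hue_nm, round(secondary_peak_prominence(s), 4))

print(round(divergence_time(0.207, 0.0043), 2), "My")
```

prints

```
branickii 576.0 0.035
gularis 506.0 0.0068
hybrid 700.0 0.0006
9.96 My
```

Both parental simulations carry a secondary reflectance peak in the
400–500 nm band (prominences 0.035 and 0.0068 relative to the spectral
maximum) that the hybrid's spectrum essentially lacks (0.0006) — the optical
signature of the hybrid's distinct gorget — and the hybrid's hue is strongly
red-shifted relative to both parents. The last line converts a gorget colour
divergence of 0.207 JND into the ≈10 My it would take to evolve within a
lineage at a Brownian rate of 0.0043 JND² My⁻¹.

The same analyses run end-to-end on synthetic data from the command line:

```bash
gorget run-all --outdir out --seed 1
```

which writes per-stage artefacts (colour distances, simulated spectra,
transgression metrics, rate and ancestry reports, suitability maps) plus a
manifest with hashes and seeds.

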