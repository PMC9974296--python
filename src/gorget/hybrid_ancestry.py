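"""SNP filtering, diagnostic loci, hybrid index and interspecific
heterozygosity.

Given biallelic genotypes for two parental reference panels and one or more
focal individuals, the analysis (i) drops low-confidence calls (read depth
and genotype quality), (ii) keeps ancestry-diagnostic loci — fixed for
alternative alleles between the parental panels — and (iii) summarises each
focal individual by its hybrid index h (proportion of alleles derived from
parent 2) and interspecific heterozygosity (proportion of diagnostic loci
with one allele from each parental species). In (h, het) space, genotype
classes occupy canonical positions in a triangle: parentals at the corners,
F1 at the apex, F2 mid-triangle, and backcrosses along the sides, halving
het per backcross generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "FilterConfig",
    "AncestryEstimate",
    "read_vcf",
    "filter_snps",
    "diagnostic_loci",
    "hybrid_index",
    "interspecific_heterozygosity",
    "classify_hybrid",
    "CANONICAL_CLASSES",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes: ``genotypes[locus, sample, 0:2]`` holds allele
    indices (0 = REF, 1 = ALT, −1 = missing); depth and quality are per
    call. ``populations`` maps sample -> parent1 | parent2 | focal."""

    genotypes: np.ndarray          # (L, S, 2) int8
    depth: np.ndarray              # (L, S) float, NaN when absent
    quality: np.ndarray            # (L, S) float, NaN when absent
    samples: list[str]
    populations: dict[str, str]
    locus_ids: list[str] = field(default_factory=list)
    n_multiallelic_dropped: int = 0

    def __post_init__(self):
        L, S, two = self.genotypes.shape
        if two != 2 or S != len(self.samples):
            raise ValueError("genotype array must be (loci, samples, 2)")
        missing = set(self.samples) - set(self.populations)
        if missing:
            raise ValueError(f"samples missing from population map: {sorted(missing)}")
        if not self.locus_ids:
            self.locus_ids = [f"locus{i}" for i in range(L)]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[0]

    def sample_idx(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] == population],
            dtype=int,
        )

    def subset_loci(self, mask) -> "GenotypeMatrix":
        ids = [l for l, m in zip(self.locus_ids, mask) if m]
        return GenotypeMatrix(
            genotypes=self.genotypes[mask],
            depth=self.depth[mask],
            quality=self.quality[mask],
            samples=list(self.samples),
            populations=dict(self.populations),
            locus_ids=ids,
            n_multiallelic_dropped=self.n_multiallelic_dropped,
        )


@dataclass(frozen=True)
class FilterConfig:
    """Call-confidence thresholds, applied as strict inequalities: a call
    passes only with depth > min_depth − 1 and quality > min_quality."""

    min_depth: int = 6       # i.e. depth must exceed 5×
    min_quality: float = 20.0
    require_fixed_parental_difference: bool = True

    def __post_init__(self):
        if self.min_depth < 0 or self.min_quality < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class AncestryEstimate:
    h: float
    ci_low: float
    ci_high: float
    heterozygosity: float
    n_loci: int

    def __post_init__(self):
        if not (0 <= self.ci_low <= self.h <= self.ci_high <= 1):
            raise ValueError("CI must lie in [0, 1] and contain h")


def read_vcf(path, populations: dict[str, str]) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF with cyvcf2.

    Multiallelic records are dropped (counted); missing calls stay missing.
    Every sample in the file must appear in the population map.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing = set(samples) - set(populations)
    if missing:
        raise ValueError(f"individuals missing from population map: {sorted(missing)}")
    gts, dps, gqs, ids = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        g = np.array(var.genotypes, dtype=object)
        alleles = np.array([[row[0], row[1]] for row in var.genotypes], dtype=np.int8)
        gts.append(alleles)
        def fmt(key):
            try:
                arr = var.format(key)
            except KeyError:
                arr = None
            if arr is None:
                return np.full(len(samples), np.nan)
            out = arr[:, 0].astype(float)
            out[out < 0] = np.nan  # cyvcf2 encodes missing as large negatives
            return out

        dps.append(fmt("DP"))
        gqs.append(fmt("GQ"))
        ids.append(f"{var.CHROM}:{var.POS}")
    if n_multi:
        logger.info("dropped %d multiallelic records", n_multi)
    L = len(gts)
    shape = (L, len(samples))
    return GenotypeMatrix(
        genotypes=np.array(gts, dtype=np.int8).reshape(L, len(samples), 2),
        depth=np.array(dps, dtype=float).reshape(shape),
        quality=np.array(gqs, dtype=float).reshape(shape),
        samples=samples,
        populations=dict(populations),
        locus_ids=ids,
        n_multiallelic_dropped=n_multi,
    )


def filter_snps(gm: GenotypeMatrix, cfg: FilterConfig = FilterConfig()) -> GenotypeMatrix:
    """Apply depth/quality filters.

    A call fails when depth ≤ min_depth − 1 or quality ≤ min_quality
    (strict inequalities; calls lacking DP/GQ annotations pass). Loci are
    dropped whenever any parental call fails; failing focal calls are set to
    missing.
    """
    depth_ok = ~(gm.depth <= cfg.min_depth - 1)    # NaN-safe: NaN passes
    qual_ok = ~(gm.quality <= cfg.min_quality)
    ok = depth_ok & qual_ok
    par = np.concatenate([gm.sample_idx("parent1"), gm.sample_idx("parent2")])
    keep_locus = ok[:, par].all(axis=1) if par.size else np.ones(gm.n_loci, bool)
    out = gm.subset_loci(keep_locus)
    fail = ~ok[keep_locus]
    gt = out.genotypes.copy()
    gt[fail] = MISSING
    out.genotypes = gt
    return out


def diagnostic_loci(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep loci fixed for alternative alleles between the parental panels.

    Every parent1 call must be homozygous for one allele, every parent2 call
    homozygous for the other; heterozygous or polymorphic-within-panel loci
    are dropped. Missing parental calls are ignored, but each panel needs at
    least one non-missing call at a locus for it to be retained.
    """
    i1, i2 = gm.sample_idx("parent1"), gm.sample_idx("parent2")
    if i1.size == 0 or i2.size == 0:
        raise ValueError("both parental panels must be non-empty")

    def fixed_allele(panel: np.ndarray) -> np.ndarray:
        """Per locus: the panel's fixed allele, or −1 if not fixed/no data."""
        L = panel.shape[0]
        out = np.full(L, MISSING, dtype=np.int8)
        present = panel[:, :, 0] != MISSING
        hom = present & (panel[:, :, 0] == panel[:, :, 1])
        # all present calls homozygous and identical
        for locus in range(L):
            alleles = panel[locus][present[locus]]
            if alleles.size == 0:
                continue
            if np.all(hom[locus][present[locus]]) and np.unique(alleles).size == 1:
                out[locus] = alleles.flat[0]
        return out

    a1 = fixed_allele(gm.genotypes[:, i1])
    a2 = fixed_allele(gm.genotypes[:, i2])
    keep = (a1 != MISSING) & (a2 != MISSING) & (a1 != a2)
    out = gm.subset_loci(keep)
    out.parent1_allele = a1[keep]  # type: ignore[attr-defined]
    out.parent2_allele = a2[keep]  # type: ignore[attr-defined]
    return out


def _parent2_allele(gm: GenotypeMatrix) -> np.ndarray:
    a2 = getattr(gm, "parent2_allele", None)
    if a2 is None:
        gm2 = diagnostic_loci(gm)
        if gm2.n_loci != gm.n_loci:
            raise ValueError("matrix contains non-diagnostic loci; run diagnostic_loci first")
        a2 = gm2.parent2_allele
    return a2


def _focal_calls(gm: GenotypeMatrix, focal: str):
    if focal not in gm.samples:
        raise ValueError(f"unknown individual {focal!r}")
    j = gm.samples.index(focal)
    g = gm.genotypes[:, j]
    ok = (g != MISSING).all(axis=1)
    if not ok.any():
        raise ValueError("no usable diagnostic loci for this individual")
    return g, ok


def _profile_likelihood_ci(k: int, n: int, drop: float = 1.92) -> tuple[float, float]:
    """Binomial profile-likelihood CI: {p : ℓ(p̂) − ℓ(p) ≤ drop}."""
    phat = k / n

    def ll(p):
        out = 0.0
        if k:
            out += k * np.log(p)
        if n - k:
            out += (n - k) * np.log(1 - p)
        return out

    lmax = ll(phat) if 0 < phat < 1 else 0.0
    f = lambda p: lmax - ll(p) - drop
    lo = 0.0 if k == 0 or f(1e-12) < 0 else brentq(f, 1e-12, phat)
    hi = 1.0 if k == n or f(1 - 1e-12) < 0 else brentq(f, phat, 1 - 1e-12)
    return float(lo), float(hi)


def hybrid_index(gm: GenotypeMatrix, focal: str) -> AncestryEstimate:
    """Hybrid index of a focal individual at diagnostic loci.

    h = (number of parent2-derived alleles) / (2 × non-missing loci), with a
    95% profile-likelihood CI (log-likelihood drop of 1.92) under locus
    independence.
    """
    a2 = _parent2_allele(gm)
    g, ok = _focal_calls(gm, focal)
    k = int((g[ok] == a2[ok, None]).sum())
    n = int(2 * ok.sum())
    lo, hi = _profile_likelihood_ci(k, n)
    het = float(((g[ok] == a2[ok, None]).sum(axis=1) == 1).mean())
    return AncestryEstimate(
        h=k / n, ci_low=lo, ci_high=hi, heterozygosity=het, n_loci=int(ok.sum())
    )


def interspecific_heterozygosity(gm: GenotypeMatrix, focal: str) -> float:
    """Proportion of non-missing diagnostic loci carrying one allele from
    each parental species."""
    a2 = _parent2_allele(gm)
    g, ok = _focal_calls(gm, focal)
    return float(((g[ok] == a2[ok, None]).sum(axis=1) == 1).mean())


#: canonical (h, het) positions of hybrid classes in the triangle plot
CANONICAL_CLASSES: dict[str, tuple[float, float]] = {
    "P1": (0.0, 0.0),
    "P2": (1.0, 0.0),
    "F1": (0.5, 1.0),
    "F2": (0.5, 0.5),
    "BC1_P1": (0.25, 0.5),
    "BC1_P2": (0.75, 0.5),
    "BC2_P1": (0.125, 0.25),
    "BC2_P2": (0.875, 0.25),
    "BC3_P1": (0.0625, 0.125),
    "BC3_P2": (0.9375, 0.125),
}


def classify_hybrid(
    h: float, het: float, tolerance: float = 0.05
) -> tuple[str, dict[str, float]]:
    """Nearest canonical hybrid class in (h, het) space.

    Later-generation backcrosses halve both the expected minority ancestry
    and the heterozygosity each generation. Points violating the triangle
    constraint het ≤ 2·min(h, 1−h) beyond ``tolerance`` are rejected.

    Returns (label, distances to every canonical point).
    """
    if not (0 <= h <= 1 and 0 <= het <= 1):
        raise ValueError("h and het must lie in [0, 1]")
    if het > 2 * min(h, 1 - h) + tolerance:
        raise ValueError("point lies outside the triangle beyond tolerance")
    dists = {
        lab: float(np.hypot(h - hh, het - vv))
        for lab, (hh, vv) in CANONICAL_CLASSES.items()
    }
    return min(dists, key=dists.get), dists
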