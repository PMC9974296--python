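"""Synthetic-data generators for every pipeline stage.

Each generator is a pure function of its spec (seed included): re-running
with the same spec yields byte-identical artefacts. The generators emulate
the statistical structure each downstream stage assumes — Gaussian-peaked
reflectance spectra per group, nanostructure traits normally distributed
around published per-taxon means, parental populations fixed at diagnostic
loci with Mendelian crosses, Brownian-motion traits on a Yule tree, and
smooth environmental surfaces with occurrences sampled from Gaussian niches
— without attempting to mimic any real taxon beyond those features.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import MultiPoint, mapping

from .colour_vision import ReflectanceSpectrum
from .feather_optics import NanostructureParams
from .hybrid_ancestry import GenotypeMatrix
from .niche_model import EnvRasterStack, Grid, OccurrenceSet

__all__ = [
    "SpectrumGenSpec",
    "CrossGenSpec",
    "TreeTraitGenSpec",
    "NicheGenSpec",
    "NANOSTRUCTURE_MEANS",
    "nanostructure_means",
    "gen_spectra",
    "gen_nanostructure",
    "gen_cross",
    "gen_tree_traits",
    "gen_niche_system",
    "write_vcf",
    "write_occurrences",
    "write_m_polygons",
]


# ---------------------------------------------------------------------------
# reflectance spectra

@dataclass(frozen=True)
class SpectrumGenSpec:
    """Groups of Gaussian-peaked spectra.

    Each group is (label, peak_nm, height_pct, width_nm) with an optional
    fifth element holding a secondary (peak_nm, height_pct, width_nm) triple.
    """

    groups: tuple
    n_per_group: int = 10
    noise_sd: float = 0.5
    wavelength_start: float = 300.0
    wavelength_stop: float = 700.0
    wavelength_step: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise ValueError("at least one group required")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not (300.0 <= self.wavelength_start < self.wavelength_stop <= 700.0):
            raise ValueError("wavelength range must lie within [300, 700]")
        for g in self.groups:
            if not (0 < g[2] <= 100):
                raise ValueError(f"peak height must be in (0, 100], got {g[2]}")

    def grid(self) -> np.ndarray:
        return np.arange(
            self.wavelength_start,
            self.wavelength_stop + self.wavelength_step / 2,
            self.wavelength_step,
        )


def gen_spectra(spec: SpectrumGenSpec) -> dict[str, list[ReflectanceSpectrum]]:
    """Per-group spectra: sum of Gaussian peaks plus iid noise, clipped ≥ 0."""
    rng = np.random.default_rng(spec.seed)
    wl = spec.grid()
    out: dict[str, list[ReflectanceSpectrum]] = {}
    for g in spec.groups:
        label, peak, height, width = g[0], g[1], g[2], g[3]
        base = height * np.exp(-((wl - peak) ** 2) / (2 * width**2))
        if len(g) > 4 and g[4] is not None:
            p2, h2, w2 = g[4]
            base = base + h2 * np.exp(-((wl - p2) ** 2) / (2 * w2**2))
        specs = []
        for i in range(spec.n_per_group):
            noise = rng.normal(0.0, spec.noise_sd, wl.size) if spec.noise_sd else 0.0
            r = np.clip(base + noise, 0.0, None)
            specs.append(
                ReflectanceSpectrum(wl, r, specimen_id=f"{label}_{i}", patch=label)
            )
        out[label] = specs
    return out


# ---------------------------------------------------------------------------
# nanostructure traits

# published per-taxon feather nanostructure means with 95% CI bounds (nm,
# except n_layers); within-individual variation across TEM images
_NANO_ROWS = [
    # trait, patch, taxon, mean, lo, hi
    ("air", "crown", "branickii", 87, 64, 111), ("air", "crown", "hybrid", 91, 78, 115),
    ("air", "crown", "gularis", 101, 76, 126),
    ("air", "gorget", "branickii", 126, 93, 151), ("air", "gorget", "hybrid", 149, 116, 179),
    ("air", "gorget", "gularis", 102, 65, 133),
    ("air", "tail", "branickii", 90, 67, 112), ("air", "tail", "hybrid", 89, 65, 110),
    ("air", "tail", "gularis", 79, 50, 102),
    ("cortex", "crown", "branickii", 133, 106, 153), ("cortex", "crown", "hybrid", 108, 95, 126),
    ("cortex", "crown", "gularis", 146, 124, 168),
    ("cortex", "gorget", "branickii", 173, 157, 192), ("cortex", "gorget", "hybrid", 139, 111, 164),
    ("cortex", "gorget", "gularis", 159, 129, 199),
    ("cortex", "tail", "branickii", 64, 45, 87), ("cortex", "tail", "hybrid", 52, 30, 78),
    ("cortex", "tail", "gularis", 52, 31, 77),
    ("ker", "crown", "branickii", 26, 15, 36), ("ker", "crown", "hybrid", 32, 23, 45),
    ("ker", "crown", "gularis", 32, 24, 44),
    ("ker", "gorget", "branickii", 39, 25, 66), ("ker", "gorget", "hybrid", 39, 19, 65),
    ("ker", "gorget", "gularis", 33, 20, 47),
    ("ker", "tail", "branickii", 25, 6, 37), ("ker", "tail", "hybrid", 17, 12, 22),
    ("ker", "tail", "gularis", 33, 19, 54),
    ("n_layers", "crown", "branickii", 13, 12, 14), ("n_layers", "crown", "hybrid", 16, 12, 21),
    ("n_layers", "crown", "gularis", 11, 7, 14),
    ("n_layers", "gorget", "branickii", 9, 9, 10), ("n_layers", "gorget", "hybrid", 12, 10, 14),
    ("n_layers", "gorget", "gularis", 8, 6, 10),
    ("n_layers", "tail", "branickii", 5, 4, 6), ("n_layers", "tail", "hybrid", 3, 3, 4),
    ("n_layers", "tail", "gularis", 3, 2, 3),
    ("mel", "crown", "branickii", 37, 28, 46), ("mel", "crown", "hybrid", 44, 34, 53),
    ("mel", "crown", "gularis", 39, 32, 46),
    ("mel", "gorget", "branickii", 52, 41, 65), ("mel", "gorget", "hybrid", 49, 39, 61),
    ("mel", "gorget", "gularis", 52, 40, 60),
    ("mel", "tail", "branickii", 40, 32, 48), ("mel", "tail", "hybrid", 44, 36, 58),
    ("mel", "tail", "gularis", 56, 43, 68),
    ("pt_top", "crown", "branickii", 85, 67, 107), ("pt_top", "crown", "hybrid", 91, 72, 113),
    ("pt_top", "crown", "gularis", 123, 100, 152),
    ("pt_top", "gorget", "branickii", 168, 141, 190), ("pt_top", "gorget", "hybrid", 198, 167, 224),
    ("pt_top", "gorget", "gularis", 174, 128, 206),
    ("pt_top", "tail", "branickii", 165, 132, 207), ("pt_top", "tail", "hybrid", 165, 147, 197),
    ("pt_top", "tail", "gularis", 211, 186, 229),
]

NANOSTRUCTURE_MEANS = pd.DataFrame(
    _NANO_ROWS, columns=["trait", "patch", "taxon", "mean", "ci_lo", "ci_hi"]
)


def nanostructure_means(taxon: str, patch: str) -> pd.DataFrame:
    """Trait means and CI half-widths for one taxon/patch, indexed by trait."""
    sub = NANOSTRUCTURE_MEANS.query("taxon == @taxon and patch == @patch")
    if sub.empty:
        raise ValueError(f"no entries for taxon={taxon!r}, patch={patch!r}")
    out = sub.set_index("trait")[["mean"]].copy()
    out["ci_half_width"] = (sub["ci_hi"] - sub["ci_lo"]).to_numpy() / 2.0
    return out


def gen_nanostructure(
    taxon_means: pd.DataFrame, n_images: int, seed: int = 0
) -> tuple[list[NanostructureParams], pd.DataFrame]:
    """Sample per-image nanostructure parameter sets.

    ``taxon_means`` is indexed by trait with columns ``mean`` and
    ``ci_half_width`` (95% bounds → SD = half-width/1.96). Traits draw
    independently from normals truncated at 0; layer counts round to the
    nearest integer ≥ 1.
    """
    if (taxon_means["mean"] <= 0).any():
        raise ValueError("all trait means must be positive")
    rng = np.random.default_rng(seed)
    samples = {}
    for trait, row in taxon_means.iterrows():
        mu, sd = float(row["mean"]), float(row["ci_half_width"]) / 1.96
        if sd == 0:
            samples[trait] = np.full(n_images, mu)
        else:
            a = (0.0 - mu) / sd  # truncate at zero
            samples[trait] = stats.truncnorm.rvs(
                a, np.inf, loc=mu, scale=sd, size=n_images, random_state=rng
            )
    df = pd.DataFrame(samples)
    if "n_layers" in df:
        df["n_layers"] = np.maximum(1, np.rint(df["n_layers"])).astype(int)
    if int(df.get("n_layers", pd.Series([1])).min()) < 1:
        raise ValueError("n_layers must round to >= 1")
    params = [
        NanostructureParams(
            cortex=r["cortex"], pt_top=r["pt_top"], mel=r["mel"],
            ker=r["ker"], air=r["air"], n_layers=int(r["n_layers"]),
        )
        for _, r in df.iterrows()
    ]
    return params, df


# ---------------------------------------------------------------------------
# genotype crosses

_CROSS_TYPES = ("P1", "P2", "F1", "F2", "BC1_P1", "BC1_P2")


@dataclass(frozen=True)
class CrossGenSpec:
    """Two parental panels fixed for alternative alleles plus focal crosses.

    ``cross_type`` is one of P1, P2, F1, F2, BC1_P1, BC1_P2, or BCn_P1/BCn_P2
    for later backcross generations (e.g. BC3_P1).
    """

    n_loci: int = 1000
    n_parental_per_species: int = 4
    cross_type: str = "F1"
    n_focal: int = 1
    missing_rate: float = 0.0
    depth: int = 30
    quality: int = 99
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        self.parse_cross(self.cross_type)

    @staticmethod
    def parse_cross(cross_type: str) -> tuple[str, int]:
        """Return (kind, generation): ('BC_P1', 2) for 'BC2_P1' etc."""
        if cross_type in ("P1", "P2", "F1", "F2"):
            return cross_type, 0
        if "_" in cross_type:
            head, side = cross_type.split("_", 1)
            if head.startswith("BC") and head[2:].isdigit() and side in ("P1", "P2"):
                gen = int(head[2:])
                if gen >= 1:
                    return f"BC_{side}", gen
        raise ValueError(f"unknown cross_type {cross_type!r}")


def _gamete(genotype: np.ndarray, rng) -> np.ndarray:
    """One Mendelian gamete from a (L, 2) genotype: free recombination."""
    pick = rng.integers(0, 2, size=genotype.shape[0])
    return genotype[np.arange(genotype.shape[0]), pick]


def _make_focal(kind: str, gen: int, n_loci: int, rng) -> np.ndarray:
    p1 = np.zeros((n_loci, 2), dtype=np.int8)
    p2 = np.ones((n_loci, 2), dtype=np.int8)
    f1 = np.column_stack([np.zeros(n_loci, np.int8), np.ones(n_loci, np.int8)])
    if kind == "P1":
        return p1
    if kind == "P2":
        return p2
    if kind == "F1":
        return f1
    if kind == "F2":
        return np.column_stack([_gamete(f1, rng), _gamete(f1, rng)])
    parent = p1 if kind.endswith("P1") else p2
    cur = f1
    for _ in range(gen):
        cur = np.column_stack([_gamete(cur, rng), _gamete(parent, rng)])
    return cur


def gen_cross(spec: CrossGenSpec) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a diagnostic-locus panel plus focal cross individuals.

    Parental panels are fixed (parent1 homozygous REF, parent2 homozygous
    ALT at every locus); focal individuals are built by Mendelian gamete
    sampling with free recombination. The truth table carries the realised
    (not expected) hybrid index and interspecific heterozygosity of each
    focal individual, computed before any missingness is applied.
    """
    kind, gen = CrossGenSpec.parse_cross(spec.cross_type)
    rng = np.random.default_rng(spec.seed)
    L, npar = spec.n_loci, spec.n_parental_per_species
    samples, columns, truths = [], [], []
    for i in range(npar):
        samples.append(f"p1_{i}")
        columns.append(np.zeros((L, 2), np.int8))
    for i in range(npar):
        samples.append(f"p2_{i}")
        columns.append(np.ones((L, 2), np.int8))
    for i in range(spec.n_focal):
        g = _make_focal(kind, gen, L, rng)
        h = float(g.sum()) / (2 * L)
        het = float((g.sum(axis=1) == 1).mean())
        truths.append((f"focal_{i}", spec.cross_type, h, het))
        if spec.missing_rate:
            miss = rng.random(L) < spec.missing_rate
            g = g.copy()
            g[miss] = -1
        samples.append(f"focal_{i}")
        columns.append(g)
    gt = np.stack(columns, axis=1)  # (L, S, 2)
    populations = {s: ("parent1" if s.startswith("p1") else
                       "parent2" if s.startswith("p2") else "focal")
                   for s in samples}
    gm = GenotypeMatrix(
        genotypes=gt,
        depth=np.full((L, len(samples)), float(spec.depth)),
        quality=np.full((L, len(samples)), float(spec.quality)),
        samples=samples,
        populations=populations,
    )
    truth = pd.DataFrame(truths, columns=["individual", "cross_type", "h", "het"])
    return gm, truth


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT:DP:GQ so depth/quality filters are
    exercisable downstream."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for locus in range(gm.n_loci):
            fields = ["1", str(locus + 1), gm.locus_ids[locus], "A", "T",
                      ".", "PASS", ".", "GT:DP:GQ"]
            for s in range(len(gm.samples)):
                a, b = gm.genotypes[locus, s]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                dp = gm.depth[locus, s]
                gq = gm.quality[locus, s]
                dp_s = "." if np.isnan(dp) else str(int(dp))
                gq_s = "." if np.isnan(gq) else str(int(gq))
                fields.append(f"{gt}:{dp_s}:{gq_s}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# trees and Brownian traits

@dataclass(frozen=True)
class TreeTraitGenSpec:
    """A Yule tree rescaled to a total depth, with independent Brownian
    axes of per-My variance ``sigma2_true`` each."""

    n_tips: int = 50
    total_depth: float = 20.0
    sigma2_true: float = 0.005
    n_axes: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.sigma2_true < 0:
            raise ValueError("sigma2_true must be >= 0")


def _yule_tree(n_tips: int, rng: random.Random) -> dendropy.Tree:
    from dendropy.simulate import treesim

    return treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )


def gen_tree_traits(spec: TreeTraitGenSpec) -> tuple[dendropy.Tree, pd.DataFrame]:
    """A clock-scaled Yule tree plus tip traits evolved by Brownian motion.

    Each axis accrues independent Normal(0, σ²·b) increments along every
    branch of length b; the tree is rescaled so the root-tip depth equals
    ``total_depth`` My.
    """
    py_rng = random.Random(spec.seed)
    tree = _yule_tree(spec.n_tips, py_rng)
    tree.seed_node.edge.length = None
    # the simulator stops at the n-th speciation, leaving two zero-length
    # pendant edges; grow all tips by one exponential waiting time so the
    # tree stays ultrametric with strictly positive branches
    extra = py_rng.expovariate(spec.n_tips * 1.0)
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    depth = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    factor = spec.total_depth / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    # deterministic tip labels
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon.label = f"t{i}"
    rng = np.random.default_rng(spec.seed)
    values: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.zeros(spec.n_axes)
            continue
        b = float(node.edge.length or 0.0)
        step = rng.normal(0.0, np.sqrt(spec.sigma2_true * b), spec.n_axes)
        values[node] = values[node.parent_node] + step
    rows = {
        lf.taxon.label: values[lf] for lf in tree.leaf_node_iter()
    }
    traits = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"axis{i}" for i in range(spec.n_axes)]
    )
    traits.index.name = "tip"
    return tree, traits.sort_index()


# ---------------------------------------------------------------------------
# niche systems

@dataclass(frozen=True)
class NicheGenSpec:
    """Smooth environmental surfaces plus occurrences from Gaussian niches.

    ``niche_centre`` / ``niche_cov`` map species label to the niche optimum
    and covariance in environment space (dimension = n_env_layers).
    """

    grid_shape: tuple[int, int] = (60, 80)
    n_env_layers: int = 4
    niche_centre: dict = field(default_factory=dict)
    niche_cov: dict = field(default_factory=dict)
    n_occurrences: dict | int = 100
    smooth_sigma: float = 4.0     # cells; spatial autocorrelation scale
    cellsize: float = 0.05        # degrees
    buffer_cells: float = 5.0     # M polygon buffer around occurrences
    seed: int = 0

    def __post_init__(self):
        for sp, cov in self.niche_cov.items():
            cov = np.asarray(cov, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValueError(f"niche_cov for {sp!r} must be symmetric")
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError(f"niche_cov for {sp!r} must be positive-definite")
        for sp in self.niche_centre:
            if self.occ_count(sp) < self.n_env_layers + 2:
                raise ValueError("n_occurrences must be >= n_env_layers + 2")

    def occ_count(self, species: str) -> int:
        if isinstance(self.n_occurrences, dict):
            return int(self.n_occurrences[species])
        return int(self.n_occurrences)


def gen_niche_system(spec: NicheGenSpec):
    """Generate (EnvRasterStack, {species: OccurrenceSet}, {species: polygon}).

    Environmental layers are Gaussian random fields (smoothed, standardized
    white noise). Cells are sampled with probability proportional to each
    species' Gaussian niche density evaluated at the cell environments;
    occurrences sit at cell centres. The M polygon is the convex hull of a
    species' occurrences buffered by ``buffer_cells`` cells.
    """
    if not spec.niche_centre:
        raise ValueError("at least one species with a niche_centre is required")
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.grid_shape
    grid = Grid(nrows=nrows, ncols=ncols, xll=0.0, yll=0.0, cellsize=spec.cellsize)
    layers = {}
    for i in range(spec.n_env_layers):
        field_ = ndimage.gaussian_filter(
            rng.normal(size=(nrows, ncols)), spec.smooth_sigma, mode="nearest"
        )
        field_ = (field_ - field_.mean()) / field_.std()
        layers[f"env{i}"] = field_
    stack = EnvRasterStack(layers=layers, grid=grid)
    lon_c, lat_c = grid.cell_centres()
    env_cells = np.column_stack([layers[n].ravel() for n in stack.names])
    occurrences, polygons = {}, {}
    for sp, centre in spec.niche_centre.items():
        mu = np.asarray(centre, dtype=float)
        cov = np.asarray(spec.niche_cov[sp], dtype=float)
        dens = stats.multivariate_normal(mean=mu, cov=cov).pdf(env_cells)
        if dens.sum() == 0:
            raise ValueError(f"niche of {sp!r} has no support on the grid")
        p = dens / dens.sum()
        n_occ = spec.occ_count(sp)
        pick = rng.choice(env_cells.shape[0], size=n_occ, replace=True, p=p)
        rows, cols = np.unravel_index(pick, (nrows, ncols))
        occ = OccurrenceSet(
            species=sp,
            lon=lon_c[rows, cols],
            lat=lat_c[rows, cols],
            env=env_cells[pick],
        )
        occurrences[sp] = occ
        hull = MultiPoint(list(zip(occ.lon, occ.lat))).convex_hull
        polygons[sp] = hull.buffer(spec.buffer_cells * spec.cellsize)
    return stack, occurrences, polygons


def write_occurrences(occurrences: dict[str, OccurrenceSet], path) -> None:
    rows = [
        {"species": sp, "lon": x, "lat": y}
        for sp, occ in occurrences.items()
        for x, y in zip(occ.lon, occ.lat)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_occurrences(path) -> dict[str, OccurrenceSet]:
    df = pd.read_csv(path)
    out = {}
    for sp, sub in df.groupby("species"):
        out[sp] = OccurrenceSet(
            species=str(sp),
            lon=sub["lon"].to_numpy(float),
            lat=sub["lat"].to_numpy(float),
        )
    return out


def write_m_polygons(polygons: dict, path) -> None:
    """GeoJSON FeatureCollection of per-species M polygons."""
    import json

    features = [
        {
            "type": "Feature",
            "properties": {"species": sp},
            "geometry": mapping(poly),
        }
        for sp, poly in polygons.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_m_polygons(path) -> dict:
    import json

    from shapely.geometry import shape as shapely_shape

    with open(path) as fh:
        fc = json.load(fh)
    return {
        f["properties"]["species"]: shapely_shape(f["geometry"])
        for f in fc["features"]
    }
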