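"""Presence-only ellipsoid niche models, suitability maps and niche overlap.

A species' niche is summarised by a minimum-volume ellipsoid (MVE) in
environmental space: the smallest ellipsoid (centre μ, shape Σ) covering a
stated fraction of the occurrence points' extracted environments. Cell
suitability is a monotone transform of the Mahalanobis distance
D²(x) = (x−μ)ᵀΣ⁻¹(x−μ); binary maps threshold D² at 90% data inclusion.
Niche overlap between two suitability surfaces is Schoener's D, and the
background similarity test compares observed overlap against overlap with
pseudomodels fitted to random cells drawn from the other species' accessible
area (M region).

Rasters are plain-text ESRI ASCII grids; all layers of a stack share one
grid and no-data mask.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape
from shapely import contains_xy

__all__ = [
    "Grid",
    "EnvRasterStack",
    "OccurrenceSet",
    "MVEModel",
    "SuitabilityMap",
    "OverlapResult",
    "read_ascii_grid",
    "write_ascii_grid",
    "extract_env",
    "fit_mve",
    "suitability_map",
    "schoeners_D",
    "background_similarity_test",
    "env_pca",
]


@dataclass(frozen=True)
class Grid:
    """Geographic grid: lower-left corner, square cells, row 0 at the top."""

    nrows: int
    ncols: int
    xll: float
    yll: float
    cellsize: float

    def cell_of(self, lon, lat):
        """Nearest-cell (row, col) for lon/lat arrays; out-of-grid -> -1."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cellsize).astype(int)
        row_from_bottom = np.floor((lat - self.yll) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def cell_centres(self):
        """(lon, lat) arrays of shape (nrows, ncols)."""
        x = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        y_top = self.yll + (self.nrows - 0.5) * self.cellsize
        y = y_top - np.arange(self.nrows) * self.cellsize
        return np.meshgrid(x, y)


NODATA = -9999.0


def write_ascii_grid(path, data: np.ndarray, grid: Grid) -> None:
    """Write one layer as an ESRI ASCII grid (NaN -> NODATA)."""
    out = np.where(np.isnan(data), NODATA, data)
    header = (
        f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
        f"xllcorner {grid.xll}\nyllcorner {grid.yll}\n"
        f"cellsize {grid.cellsize}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            meta[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    data = np.loadtxt(lines[i:])
    data = np.atleast_2d(data)
    nodata = meta.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    grid = Grid(
        nrows=int(meta["nrows"]), ncols=int(meta["ncols"]),
        xll=meta["xllcorner"], yll=meta["yllcorner"], cellsize=meta["cellsize"],
    )
    if data.shape != (grid.nrows, grid.ncols):
        raise ValueError("grid dimensions disagree with header")
    return data, grid


@dataclass
class EnvRasterStack:
    """Aligned environmental layers sharing one grid and no-data mask."""

    layers: dict[str, np.ndarray]
    grid: Grid

    def __post_init__(self):
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError("all layers must share a shape")
        if shapes.pop() != (self.grid.nrows, self.grid.ncols):
            raise ValueError("layer shape disagrees with grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def data_mask(self) -> np.ndarray:
        m = np.ones((self.grid.nrows, self.grid.ncols), dtype=bool)
        for a in self.layers.values():
            m &= ~np.isnan(a)
        return m

    def env_at(self, rows, cols) -> np.ndarray:
        return np.column_stack([self.layers[n][rows, cols] for n in self.names])

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, a in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", a, self.grid)

    @classmethod
    def read(cls, directory) -> "EnvRasterStack":
        directory = Path(directory)
        layers, grid = {}, None
        for p in sorted(directory.glob("*.asc")):
            data, g = read_ascii_grid(p)
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError("layers have differing grids")
            layers[p.stem] = data
        if not layers:
            raise ValueError(f"no .asc layers in {directory}")
        return cls(layers=layers, grid=grid)


@dataclass
class OccurrenceSet:
    species: str
    lon: np.ndarray
    lat: np.ndarray
    env: np.ndarray | None = None   # (n, d) extracted environments
    n_dropped: int = 0

    def __len__(self):
        return self.lon.size


@dataclass(frozen=True)
class MVEModel:
    centre: np.ndarray
    shape: np.ndarray       # Σ, symmetric positive-definite
    coverage: float
    t_cover: float          # Mahalanobis D² enclosing ⌈coverage·n⌉ points
    t90: float              # D² at 90% data inclusion

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        R = np.atleast_2d(X) - self.centre
        return np.einsum("ij,jk,ik->i", R, np.linalg.inv(self.shape), R)


@dataclass
class SuitabilityMap:
    suitability: np.ndarray   # continuous in [0, 1], NaN off-data
    binary: np.ndarray        # bool, False off-data
    grid: Grid


@dataclass(frozen=True)
class OverlapResult:
    D_observed: float
    null: np.ndarray
    p_value: float
    n_reps: int
    seed: int | None


def extract_env(occ: OccurrenceSet, stack: EnvRasterStack) -> OccurrenceSet:
    """Nearest-cell environmental extraction; points off the grid or on
    no-data cells are dropped (counted)."""
    row, col = stack.grid.cell_of(occ.lon, occ.lat)
    ok = row >= 0
    mask = stack.data_mask()
    ok &= np.where(ok, mask[row.clip(0), col.clip(0)], False)
    if not ok.any():
        raise ValueError("all occurrence points fall off the data grid")
    env = stack.env_at(row[ok], col[ok])
    return OccurrenceSet(
        species=occ.species,
        lon=occ.lon[ok],
        lat=occ.lat[ok],
        env=env,
        n_dropped=int((~ok).sum()),
    )


def _candidate_volume(sigma: np.ndarray, t: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return math.inf
    d = sigma.shape[0]
    return 0.5 * logdet + 0.5 * d * math.log(t)  # log-volume up to constants


def fit_mve(
    env: np.ndarray,
    coverage: float = 0.9,
    n_subsets: int = 500,
    seed: int | None = None,
    method: str = "mve",
) -> MVEModel:
    """Robust minimum-volume ellipsoid of the occurrence environments.

    Candidate ellipsoids take the mean and covariance of (d+1)-point
    subsets, inflated to cover ⌈coverage·n⌉ points; the candidate of minimal
    volume wins. All subsets are enumerated when n ≤ 30, otherwise
    ``n_subsets`` random subsets are drawn. ``method='classical'`` returns
    the plain mean/covariance ellipsoid instead.
    """
    X = np.asarray(env, dtype=float)
    n, d = X.shape
    if n < d + 2:
        raise ValueError(f"need at least {d + 2} points to fit a {d}-D ellipsoid")
    if not (0.5 < coverage <= 1):
        raise ValueError("coverage must be in (0.5, 1]")
    k_cover = math.ceil(coverage * n)

    def finalise(mu, sigma):
        R = X - mu
        d2 = np.einsum("ij,jk,ik->i", R, np.linalg.inv(sigma), R)
        t_cover = float(np.sort(d2)[k_cover - 1])
        t90 = float(np.sort(d2)[math.ceil(0.9 * n) - 1])
        return mu, sigma, t_cover, t90

    if method == "classical":
        mu, sigma, t_cover, t90 = finalise(X.mean(axis=0), np.cov(X, rowvar=False))
        return MVEModel(mu, sigma, coverage, t_cover, t90)
    if method != "mve":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    # enumerate exhaustively when that is no dearer than sampling
    if math.comb(n, d + 1) <= max(n_subsets, 5000):
        subsets = itertools.combinations(range(n), d + 1)
    else:
        subsets = (rng.choice(n, size=d + 1, replace=False) for _ in range(n_subsets))
    best = None
    n_singular = 0
    for idx in subsets:
        S = X[list(idx)]
        mu = S.mean(axis=0)
        sigma = np.cov(S, rowvar=False)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0 or logdet < -60:  # singular or numerically degenerate
            n_singular += 1
            continue
        Si = np.linalg.inv(sigma)
        R = X - mu
        d2 = np.einsum("ij,jk,ik->i", R, Si, R)
        t = np.sort(d2)[k_cover - 1]
        if t <= 0:
            n_singular += 1
            continue
        vol = _candidate_volume(sigma, float(t))
        if best is None or vol < best[0]:
            best = (vol, mu, sigma)
    if best is None:
        raise ValueError("all candidate subsets were singular")
    mu, sigma = best[1], best[2]
    # reweighting step (standard for robust ellipsoid estimators): refit the
    # mean and covariance from the ⌈coverage·n⌉ points the winning ellipsoid
    # covers, then undo the truncation bias so that under multivariate
    # normality Σ is commensurate with the full covariance
    from scipy.stats import chi2

    R = X - mu
    d2 = np.einsum("ij,jk,ik->i", R, np.linalg.inv(sigma), R)
    covered = np.argsort(d2)[:k_cover]
    mu = X[covered].mean(axis=0)
    sigma = np.cov(X[covered], rowvar=False)
    q = chi2.ppf(coverage, d)
    sigma = sigma * (coverage / chi2.cdf(q, d + 2))
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("degenerate covered-point covariance")
    mu, sigma, t_cover, t90 = finalise(mu, sigma)
    return MVEModel(mu, sigma, coverage, t_cover, t90)


def suitability_map(model: MVEModel, stack: EnvRasterStack) -> SuitabilityMap:
    """Continuous suitability s = exp(−D²/2) and the binary 90%-inclusion
    map {D² ≤ t90} over the data cells."""
    mask = stack.data_mask()
    rows, cols = np.nonzero(mask)
    d2 = model.mahalanobis_sq(stack.env_at(rows, cols))
    suit = np.full(mask.shape, np.nan)
    suit[rows, cols] = np.exp(-d2 / 2.0)
    binary = np.zeros(mask.shape, dtype=bool)
    binary[rows, cols] = d2 <= model.t90
    return SuitabilityMap(suitability=suit, binary=binary, grid=stack.grid)


def schoeners_D(map_a, map_b, mode: str = "continuous") -> float:
    """Schoener's D = 1 − ½ Σ|p_A − p_B| over shared data cells, with each
    surface normalised to sum 1. Accepts SuitabilityMap or raw arrays."""
    def surface(m):
        if isinstance(m, SuitabilityMap):
            return m.binary.astype(float) if mode == "binary" else m.suitability
        return np.asarray(m, dtype=float)

    a, b = surface(map_a), surface(map_b)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("zero-sum suitability surface")
    pa, pb = a / a.sum(), b / b.sum()
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def _cells_in_polygon(stack: EnvRasterStack, polygon) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(polygon, dict):
        polygon = shapely_shape(polygon)
    lon, lat = stack.grid.cell_centres()
    inside = contains_xy(polygon, lon, lat) & stack.data_mask()
    return np.nonzero(inside)


def background_similarity_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    m_a,
    stack: EnvRasterStack,
    n_reps: int = 99,
    coverage: float = 0.9,
    seed: int | None = None,
    mode: str = "continuous",
    mve_subsets: int = 200,
) -> OverlapResult:
    """One direction of the background similarity test.

    The observed D compares the two species' fitted suitability surfaces.
    The null draws |occ_a| random data cells inside species A's accessible
    area ``m_a`` (GeoJSON-like mapping or shapely polygon), fits a
    pseudomodel, and compares it with species B's true model; the p-value is
    the proportion of null D values at least as large as the observed one
    (add-one convention). Small p supports niche similarity beyond what the
    available background explains.
    """
    if n_reps < 99:
        raise ValueError("use at least 99 replicates")
    if occ_a.env is None or occ_b.env is None:
        raise ValueError("occurrences need extracted environments (extract_env)")
    rng = np.random.default_rng(seed)
    model_a = fit_mve(occ_a.env, coverage=coverage, n_subsets=mve_subsets,
                      seed=int(rng.integers(2**31)))
    model_b = fit_mve(occ_b.env, coverage=coverage, n_subsets=mve_subsets,
                      seed=int(rng.integers(2**31)))
    map_b = suitability_map(model_b, stack)
    d_obs = schoeners_D(suitability_map(model_a, stack), map_b, mode=mode)
    rows, cols = _cells_in_polygon(stack, m_a)
    n_draw = len(occ_a)
    if rows.size < n_draw:
        raise ValueError("M region has fewer data cells than occurrence points")
    null = np.empty(n_reps)
    for r in range(n_reps):
        pick = rng.choice(rows.size, size=n_draw, replace=False)
        env = stack.env_at(rows[pick], cols[pick])
        pseudo = fit_mve(env, coverage=coverage, n_subsets=mve_subsets,
                         seed=int(rng.integers(2**31)))
        null[r] = schoeners_D(suitability_map(pseudo, stack), map_b, mode=mode)
    p = (1 + int((null >= d_obs).sum())) / (n_reps + 1)
    return OverlapResult(
        D_observed=float(d_obs), null=null, p_value=float(p),
        n_reps=n_reps, seed=seed,
    )


def env_pca(env_matrices, names=None):
    """PCA of pooled, centred and scaled environment matrices (delegates to
    :func:`gorget.trait_divergence.pca`)."""
    from .trait_divergence import pca

    X = np.vstack([np.asarray(m, dtype=float) for m in env_matrices])
    cols = list(names) if names else [f"env{i}" for i in range(X.shape[1])]
    return pca(pd.DataFrame(X, columns=cols), centre=True, scale=True)
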