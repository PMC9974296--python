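"""Avian colour vision: quantum catches, tetrahedral colour space and
receptor-noise-limited (RNL) discriminability.

The module models a tetrachromatic (UVS-type) visual system. A reflectance
spectrum R(λ) is turned into cone quantum catches

    q_i = ∫ R(λ) C_i(λ) I(λ) dλ,

where C_i is the spectral sensitivity of cone class i ∈ {u, s, m, l} and I is
the illuminant. Relative catches place a stimulus inside the avian tetrahedral
colour space; perceptual distances between stimuli are computed with the
receptor-noise-limited model in just-noticeable-difference (JND) units, with
channel noise e_i = ω·√(n_ref / n_i) set by the Weber fraction ω of the most
abundant cone class and the relative cone densities n_i.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReflectanceSpectrum",
    "VisualSystem",
    "QuantumCatch",
    "ColourPoint",
    "ColourDistance",
    "pigment_template",
    "read_spectra",
    "write_spectra",
    "hue_peak",
    "quantum_catches",
    "tetra_coords",
    "receptor_noise_distance",
    "noise_scaled_coords",
    "bootstrap_group_distance",
]

WL_MIN, WL_MAX = 300.0, 700.0

CONE_CLASSES = ("u", "s", "m", "l")

#: default peak sensitivities (nm) of a UVS-type hummingbird retina
DEFAULT_LAMBDA_MAX = {"u": 370.0, "s": 440.0, "m": 508.0, "l": 560.0}

#: default relative cone densities u:s:m:l
DEFAULT_DENSITIES = {"u": 1.0, "s": 2.0, "m": 2.0, "l": 4.0}


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A reflectance spectrum in percent on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    specimen_id: str = ""
    patch: str = ""          # crown | gorget | tail (free-form accepted)
    geometry: str = ""       # normal | max-reflectance angle

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or wl.shape != r.shape:
            raise ValueError("wavelengths and reflectance must be matching 1-D arrays")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(r < 0):
            raise ValueError(
                f"negative reflectance in spectrum {self.specimen_id!r}"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)


def _govardovskii_alpha_beta(wl: np.ndarray, lmax: float) -> np.ndarray:
    """Visual-pigment absorbance template (alpha plus beta band)."""
    x = lmax / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lmax
    bb = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((wl - lmb) / bb) ** 2))
    return alpha + beta


def pigment_template(wl: np.ndarray, lmax: float, normalise: str = "area") -> np.ndarray:
    """Cone spectral sensitivity from a standard visual-pigment nomogram.

    Parameters
    ----------
    wl : wavelength grid in nm
    lmax : wavelength of peak sensitivity in nm
    normalise : 'area' (unit integral), 'peak' (max 1) or 'none'
    """
    s = _govardovskii_alpha_beta(np.asarray(wl, dtype=float), float(lmax))
    s = np.clip(s, 0.0, None)
    if normalise == "area":
        s = s / np.trapezoid(s, wl)
    elif normalise == "peak":
        s = s / s.max()
    elif normalise != "none":
        raise ValueError(f"unknown normalisation {normalise!r}")
    return s


@dataclass
class VisualSystem:
    """A receptor-noise-limited tetrachromatic visual system.

    Sensitivities are sampled on ``wavelengths``; densities give relative cone
    abundances and ``weber`` the Weber fraction of the reference (most
    abundant) cone class.
    """

    wavelengths: np.ndarray
    sensitivities: dict[str, np.ndarray]
    densities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    weber: float = 0.1
    reference_cone: str = "l"
    illuminant: np.ndarray | None = None  # flat if None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.weber <= 0:
            raise ValueError("Weber fraction must be positive")
        for c, s in self.sensitivities.items():
            s = np.asarray(s, dtype=float)
            if np.any(s < 0):
                raise ValueError(f"negative sensitivity for cone {c!r}")
            self.sensitivities[c] = s
        if any(d <= 0 for d in self.densities.values()):
            raise ValueError("cone densities must be positive")
        if self.reference_cone not in self.sensitivities:
            raise ValueError("reference cone missing from sensitivities")

    @property
    def cones(self) -> tuple[str, ...]:
        return tuple(c for c in CONE_CLASSES if c in self.sensitivities) or tuple(
            self.sensitivities
        )

    def noise(self) -> np.ndarray:
        """Channel noise e_i = ω·√(n_ref / n_i), ordered as self.cones."""
        n_ref = self.densities[self.reference_cone]
        return np.array(
            [self.weber * np.sqrt(n_ref / self.densities[c]) for c in self.cones]
        )

    @classmethod
    def uvs_template(
        cls,
        wl_step: float = 1.0,
        lambda_max: dict[str, float] | None = None,
        **kwargs,
    ) -> "VisualSystem":
        """Built-in UVS system from nomogram templates (u 370, s 440, m 508,
        l 560 nm by default)."""
        wl = np.arange(WL_MIN, WL_MAX + wl_step / 2, wl_step)
        lm = dict(DEFAULT_LAMBDA_MAX)
        if lambda_max:
            lm.update(lambda_max)
        sens = {c: pigment_template(wl, lm[c]) for c in CONE_CLASSES}
        return cls(wavelengths=wl, sensitivities=sens, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "VisualSystem":
        """Load measured sensitivity curves from a CSV with columns
        ``wavelength_nm,u,s,m,l``."""
        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns:
            raise ValueError("sensitivity CSV must have a 'wavelength_nm' column")
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        sens = {
            c: df[c].to_numpy(dtype=float) for c in CONE_CLASSES if c in df.columns
        }
        return cls(wavelengths=wl, sensitivities=sens, **kwargs)


@dataclass(frozen=True)
class QuantumCatch:
    """Absolute and relative (unit-sum) cone quantum catches."""

    absolute: np.ndarray  # ordered as vs.cones
    cones: tuple[str, ...]

    @property
    def relative(self) -> np.ndarray:
        return self.absolute / self.absolute.sum()


@dataclass(frozen=True)
class ColourPoint:
    """A 3-D point, either raw tetrahedral coordinates (dimensionless) or
    noise-scaled coordinates in JND units."""

    xyz: np.ndarray
    units: str = "tetrahedral"  # or "jnd"


@dataclass(frozen=True)
class ColourDistance:
    """A receptor-noise distance in JND, optionally with a bootstrap CI."""

    delta_s: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None

    @property
    def significant(self) -> bool | None:
        """True when the CI lower bound clears the 1-JND discrimination
        threshold; None when no CI was computed."""
        if self.ci_low is None:
            return None
        return self.ci_low > 1.0


# ---------------------------------------------------------------------------
# spectra I/O


def write_spectra(spectra, path) -> None:
    """Write spectra to CSV: column 1 ``wavelength_nm``, one column per
    specimen. All spectra must share a grid."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to write")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("spectra must share a wavelength grid to be written")
    df = pd.DataFrame({"wavelength_nm": wl})
    for s in spectra:
        df[s.specimen_id] = s.reflectance
    df.to_csv(path, index=False)


def read_spectra(path) -> list[ReflectanceSpectrum]:
    """Read spectra from the CSV dialect written by :func:`write_spectra`.

    Wavelengths outside the bird-visible 300–700 nm band are trimmed with a
    warning; negative reflectance raises, naming the offending specimen.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError("first column must be 'wavelength_nm'")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    keep = (wl >= WL_MIN) & (wl <= WL_MAX)
    if not keep.all():
        logger.warning(
            "trimmed %d wavelengths outside [%g, %g] nm",
            int((~keep).sum()), WL_MIN, WL_MAX,
        )
    out = []
    for col in df.columns[1:]:
        r = df[col].to_numpy(dtype=float)[keep]
        if np.any(r < 0):
            raise ValueError(f"negative reflectance in spectrum {col!r}")
        out.append(ReflectanceSpectrum(wl[keep], r, specimen_id=str(col)))
    return out


# ---------------------------------------------------------------------------
# spectral summaries and visual modelling


def hue_peak(spectrum: ReflectanceSpectrum, smoothing_span: float = 0.0) -> float:
    """Hue as the wavelength of peak reflectance.

    ``smoothing_span`` (nm) applies a centred box filter before locating the
    maximum; ties resolve to the shortest wavelength.
    """
    r = spectrum.reflectance
    if not np.any(r > 0):
        raise ValueError("hue undefined for an all-zero spectrum")
    if smoothing_span > 0:
        step = float(np.median(np.diff(spectrum.wavelengths)))
        w = max(1, int(round(smoothing_span / step)))
        if w % 2 == 0:
            w += 1
        kernel = np.ones(w) / w
        pad = w // 2
        rp = np.pad(r, pad, mode="edge")
        r = np.convolve(rp, kernel, mode="valid")
    # argmax returns the first maximum: shortest wavelength on an increasing grid
    return float(spectrum.wavelengths[int(np.argmax(r))])


def _interp_to(wl_target, wl_source, y):
    if np.array_equal(wl_target, wl_source):
        return y
    return np.interp(wl_target, wl_source, y)


def quantum_catches(
    spectrum: ReflectanceSpectrum, vs: VisualSystem
) -> QuantumCatch:
    """Cone quantum catches by trapezoid integration of R·C_i·I on the
    spectrum grid."""
    wl = spectrum.wavelengths
    illum = (
        np.ones_like(wl)
        if vs.illuminant is None
        else _interp_to(wl, vs.wavelengths, vs.illuminant)
    )
    q = []
    for c in vs.cones:
        sens = _interp_to(wl, vs.wavelengths, vs.sensitivities[c])
        q.append(np.trapezoid(spectrum.reflectance * sens * illum, wl))
    q = np.asarray(q)
    if np.any(q <= 0):
        bad = [c for c, v in zip(vs.cones, q) if v <= 0]
        raise ValueError(f"zero quantum catch for cone(s) {bad}")
    return QuantumCatch(absolute=q, cones=vs.cones)


def tetra_coords(relative_catches) -> ColourPoint:
    """Tetrahedral colour-space coordinates from relative catches (u, s, m, l).

    Convention: the u vertex sits on +Z at 0.75 and the achromatic point at
    the origin.
    """
    rc = np.asarray(relative_catches, dtype=float)
    if rc.shape != (4,):
        raise ValueError("expected four relative catches (u, s, m, l)")
    if abs(rc.sum() - 1.0) > 1e-9:
        raise ValueError("relative catches must sum to 1")
    u, s, m, _l = rc
    x = ((1.0 - 2.0 * s - m - u) / 2.0) * np.sqrt(1.5)
    y = (-1.0 + 3.0 * m + u) / (2.0 * np.sqrt(2.0))
    z = u - 0.25
    return ColourPoint(np.array([x, y, z]), units="tetrahedral")


def _rnl_quadratic_form(noise: np.ndarray) -> tuple[np.ndarray, float]:
    """Matrix Q and denominator such that ΔS² = Δf' Q Δf / den.

    Numerator: Σ over cone pairs (j, k) of (product of the other channels'
    noise)²·(Δf_j − Δf_k)²; denominator: Σ over (n−1)-subsets of squared
    noise products. Valid for any number of channels ≥ 2.
    """
    n = noise.size
    idx = range(n)
    Q = np.zeros((n, n))
    for j, k in itertools.combinations(idx, 2):
        others = [i for i in idx if i not in (j, k)]
        c = np.prod(noise[others]) ** 2 if others else 1.0
        d = np.zeros(n)
        d[j], d[k] = 1.0, -1.0
        Q += c * np.outer(d, d)
    den = sum(
        np.prod(noise[list(sub)]) ** 2
        for sub in itertools.combinations(idx, n - 1)
    )
    return Q, den


def receptor_noise_distance(
    qa: QuantumCatch | np.ndarray,
    qb: QuantumCatch | np.ndarray,
    vs: VisualSystem,
) -> ColourDistance:
    """Receptor-noise-limited distance ΔS (JND) between two catch vectors."""
    a = qa.absolute if isinstance(qa, QuantumCatch) else np.asarray(qa, dtype=float)
    b = qb.absolute if isinstance(qb, QuantumCatch) else np.asarray(qb, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("quantum catches must be positive")
    df = np.log(a) - np.log(b)
    Q, den = _rnl_quadratic_form(vs.noise())
    return ColourDistance(delta_s=float(np.sqrt(df @ Q @ df / den)))


def _noise_metric_factor(vs: VisualSystem) -> tuple[np.ndarray, np.ndarray]:
    """Basis V of the subspace ⟂ (1,…,1) and Cholesky factor L with
    V' Q V / den = L L'."""
    noise = vs.noise()
    n = noise.size
    Q, den = _rnl_quadratic_form(noise)
    ones = np.ones((n, 1)) / np.sqrt(n)
    # orthonormal complement of the all-ones direction
    full, _ = np.linalg.qr(np.hstack([ones, np.eye(n)[:, : n - 1]]))
    V = full[:, 1:n]
    L = np.linalg.cholesky(V.T @ Q @ V / den)
    return V, L


def noise_scaled_coords(
    q: QuantumCatch | np.ndarray, vs: VisualSystem
) -> ColourPoint:
    """Coordinates in a perceptually uniform space (JND units): Euclidean
    distances between transformed points equal :func:`receptor_noise_distance`.

    The receptor-noise metric on log catches is degenerate along (1,…,1)
    (intensity); the transform restricts to the orthogonal complement and
    applies the Cholesky factor of the restricted metric.
    """
    a = q.absolute if isinstance(q, QuantumCatch) else np.asarray(q, dtype=float)
    if np.any(a <= 0):
        raise ValueError("quantum catches must be positive")
    x = np.log(a)
    x = x - x.mean()  # remove the intensity direction for numerical hygiene
    V, L = _noise_metric_factor(vs)
    return ColourPoint(L.T @ (V.T @ x), units="jnd")


def _geometric_mean_catches(catches: np.ndarray) -> np.ndarray:
    """Geometric mean over specimens (rows) of a catches matrix."""
    return np.exp(np.mean(np.log(catches), axis=0))


def bootstrap_group_distance(
    group_a,
    group_b,
    vs: VisualSystem,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ColourDistance:
    """Bootstrap the colour distance between two groups of spectra.

    Specimens are resampled with replacement within each group; each
    replicate's distance is the RNL ΔS between the groups' geometric-mean
    quantum catches. Reports the bootstrap mean and percentile 95% CI; the
    contrast is flagged significant when the CI lower bound exceeds 1 JND.
    """
    ga = list(group_a)
    gb = list(group_b)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 spectra")
    qa = np.vstack([quantum_catches(s, vs).absolute for s in ga])
    qb = np.vstack([quantum_catches(s, vs).absolute for s in gb])
    rng = np.random.default_rng(seed)
    dists = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.integers(0, len(ga), size=len(ga))
        ib = rng.integers(0, len(gb), size=len(gb))
        dists[i] = receptor_noise_distance(
            _geometric_mean_catches(qa[ia]), _geometric_mean_catches(qb[ib]), vs
        ).delta_s
    lo, hi = np.percentile(dists, [2.5, 97.5])
    return ColourDistance(
        delta_s=float(dists.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )
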