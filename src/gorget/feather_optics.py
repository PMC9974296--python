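"""One-dimensional optical model of iridescent feather barbules.

Hummingbird barbules contain stacks of flattened, hollow (air-filled)
melanosome platelets separated by keratin, beneath an outer keratin cortex.
The model discretises this cross-section into thin depth slices, assigns each
slice a uniform effective refractive index (volume-fraction-weighted mean of
the component indices), and computes specular reflectance with the standard
transfer-matrix (characteristic matrix) method.

Geometry, from the incident air side:

    air | cortex (keratin) | top platelet | [ker gap | inner platelet] × (n−1) | keratin substrate

An inner platelet is a melanin wall of mel/2, an air core of extent ``air``,
and a second mel/2 wall. The air core's lateral air fraction per slice is
constant (``block`` shape) or parabolic (``sphere`` shape, peaking at the core
midplane). The top platelet is solid melanin of thickness ``pt_top`` by
default, or the same sandwich construction when ``top_platelet_solid`` is
False.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NanostructureParams",
    "MaterialDispersion",
    "DispersionSet",
    "DEFAULT_DISPERSION",
    "LayerStack",
    "SimulatedSpectrum",
    "material_index",
    "build_stack",
    "tmm_reflectance",
    "simulate_feather_spectrum",
    "scale_params",
    "params_from_means",
    "secondary_peak_prominence",
    "compare_model_to_empirical",
]


@dataclass(frozen=True)
class NanostructureParams:
    """Per-image nanostructure means, lengths in nm."""

    cortex: float        # keratin cortex thickness
    pt_top: float        # thickness of top surficial melanosomes
    mel: float           # melanin thickness per platelet (split into 2 walls)
    ker: float           # keratin spacing between platelets
    air: float           # air space diameter (mean of parallel/perpendicular)
    n_layers: int        # number of melanosome layers
    air_shape: str = "block"        # block | sphere
    lateral_fill: float = 1.0       # φ, lateral air packing fraction
    top_platelet_solid: bool = True

    def __post_init__(self):
        for name in ("cortex", "pt_top", "mel", "ker", "air"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not (0 < self.lateral_fill <= 1):
            raise ValueError("lateral_fill must be in (0, 1]")
        if self.air_shape not in ("block", "sphere"):
            raise ValueError(f"unknown air_shape {self.air_shape!r}")


@dataclass(frozen=True)
class MaterialDispersion:
    """Cauchy dispersion n(λ) = A + B/λ² with exponential absorption
    k(λ) = k0·exp(−λ/λk). A dimensionless, B in nm²."""

    A: float
    B: float = 0.0
    k0: float = 0.0
    lambda_k: float = 270.0

    def __post_init__(self):
        if self.A < 1 or self.B < 0 or self.k0 < 0:
            raise ValueError("require A >= 1, B >= 0, k0 >= 0")

    def index(self, wl) -> np.ndarray | complex:
        wl = np.asarray(wl, dtype=float)
        n = self.A + self.B / wl**2
        k = self.k0 * np.exp(-wl / self.lambda_k) if self.k0 else np.zeros_like(wl)
        out = n + 1j * k
        return out if out.ndim else complex(out)


@dataclass(frozen=True)
class DispersionSet:
    """Configurable material optical constants.

    Defaults are generic film values for keratin and eumelanin and may be
    replaced per analysis (e.g. per-patch melanin).
    """

    keratin: MaterialDispersion = field(
        default_factory=lambda: MaterialDispersion(A=1.532, B=5890.0)
    )
    melanin: MaterialDispersion = field(
        default_factory=lambda: MaterialDispersion(
            A=1.648, B=23700.0, k0=0.56, lambda_k=270.0
        )
    )


DEFAULT_DISPERSION = DispersionSet()


def material_index(material: str, wl, dispersion: DispersionSet = DEFAULT_DISPERSION):
    """Complex refractive index of keratin, melanin or air at λ (nm)."""
    if material == "air":
        wl = np.asarray(wl, dtype=float)
        out = np.ones_like(wl) + 0j
        return out if out.ndim else complex(out)
    if material == "keratin":
        return dispersion.keratin.index(wl)
    if material == "melanin":
        return dispersion.melanin.index(wl)
    raise ValueError(f"unknown material {material!r}")


@dataclass(frozen=True)
class LayerStack:
    """Ordered finite slices between semi-infinite incident and substrate
    media. Thicknesses in nm; indices complex."""

    thicknesses: np.ndarray
    indices: np.ndarray
    n_incident: complex = 1.0 + 0j
    n_substrate: complex = 1.0 + 0j

    def __post_init__(self):
        t = np.asarray(self.thicknesses, dtype=float)
        n = np.asarray(self.indices, dtype=complex)
        if t.shape != n.shape:
            raise ValueError("thicknesses and indices must align")
        if np.any(t <= 0):
            raise ValueError("slice thicknesses must be positive")
        object.__setattr__(self, "thicknesses", t)
        object.__setattr__(self, "indices", n)


@dataclass(frozen=True)
class SimulatedSpectrum:
    wavelengths: np.ndarray
    reflectance: np.ndarray  # fraction in [0, 1]
    hue_nm: float


def _air_fraction_profile(p: NanostructureParams, z: np.ndarray) -> np.ndarray:
    """Lateral air fraction at signed depths z (nm) from the air-core centre."""
    phi = p.lateral_fill
    if p.air_shape == "block":
        return np.full_like(z, phi)
    # sphere: circular cross-section → parabolic area fraction profile
    return phi * (1.0 - (2.0 * z / p.air) ** 2)


def _segments(p: NanostructureParams):
    """Yield (thickness, kind) segments top-down; kind ∈ {keratin, melanin, core}."""
    if p.cortex > 0:
        yield p.cortex, "keratin"
    platelets = [("top", p.pt_top if p.top_platelet_solid else None)]
    platelets += [("inner", None)] * (p.n_layers - 1)
    first = True
    for tag, solid_t in platelets:
        if not first:
            if p.ker > 0:
                yield p.ker, "keratin"
        first = False
        if tag == "top" and solid_t is not None:
            if solid_t > 0:
                yield solid_t, "melanin"
        else:
            if p.mel > 0:
                yield p.mel / 2.0, "melanin"
            if p.air > 0:
                yield p.air, "core"
            if p.mel > 0:
                yield p.mel / 2.0, "melanin"


def build_stack(
    p: NanostructureParams,
    wl: float,
    slice_thickness: float = 1.0,
    dispersion: DispersionSet = DEFAULT_DISPERSION,
) -> LayerStack:
    """Discretise the barbule cross-section into uniform-index depth slices
    at one wavelength.

    Homogeneous segments (cortex, melanin walls, keratin gaps) become single
    slices; air cores are sliced at ``slice_thickness`` and each slice's index
    is the air-fraction-weighted arithmetic mean of air and melanin indices.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be positive")
    n_ker = complex(material_index("keratin", wl, dispersion))
    n_mel = complex(material_index("melanin", wl, dispersion))
    n_air = 1.0 + 0j
    thick, idx = [], []
    for t, kind in _segments(p):
        if kind == "keratin":
            thick.append(t)
            idx.append(n_ker)
        elif kind == "melanin":
            thick.append(t)
            idx.append(n_mel)
        else:  # air core, sliced
            m = max(1, int(round(t / slice_thickness)))
            edges = np.linspace(-t / 2.0, t / 2.0, m + 1)
            mids = 0.5 * (edges[:-1] + edges[1:])
            frac = np.clip(_air_fraction_profile(p, mids), 0.0, 1.0)
            for dz, f in zip(np.diff(edges), frac):
                thick.append(dz)
                idx.append(f * n_air + (1.0 - f) * n_mel)
    return LayerStack(
        thicknesses=np.asarray(thick),
        indices=np.asarray(idx, dtype=complex),
        n_incident=1.0 + 0j,
        n_substrate=n_ker,
    )


def _tmm_one_pol(n, d, n0, ns, wl, cos0, pol: str):
    """Transfer-matrix reflectance for one polarisation, vectorised over λ.

    Interface/propagation recursion in the n + ik absorbing convention
    (forward wave ∝ exp(i·2π n z/λ), so Im(n) > 0 decays). Transmission
    prefactors are dropped — they cancel in the reflection ratio.

    ``n`` has shape (L,) or (L, W) for W wavelengths; ``wl`` is scalar or
    (W,); returns reflectance of shape () or (W,).
    """
    wl = np.asarray(wl, dtype=float)
    L = len(d)
    n = np.asarray(n, dtype=complex)
    if n.ndim == 1 and wl.ndim == 1:
        n = np.broadcast_to(n[:, None], (L, wl.size))
    sin0 = np.sqrt(1.0 - cos0**2 + 0j)

    def cos_in(nj):
        s = n0 * sin0 / nj
        c = np.sqrt(1.0 - s**2 + 0j)
        # pick the decaying branch for evanescent/absorbing media
        return np.where((nj * c).imag < 0, -c, c)

    def eta(nj, cj):
        return nj * cj if pol == "s" else nj / cj

    eta_prev = eta(np.asarray(n0, dtype=complex), cos0)
    m00 = np.ones_like(wl, dtype=complex) if wl.ndim else np.ones((), complex)
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for j in range(L + 1):
        nj = np.asarray(ns, dtype=complex) if j == L else n[j]
        cj = cos_in(nj)
        ej = eta(nj, cj)
        r_if = (eta_prev - ej) / (eta_prev + ej)
        # M @ [[1, r], [r, 1]]
        m00, m01 = m00 + m01 * r_if, m00 * r_if + m01
        m10, m11 = m10 + m11 * r_if, m10 * r_if + m11
        if j < L:
            ph = np.exp(-1j * 2.0 * np.pi * nj * cj * d[j] / wl)
            m00, m01 = m00 * ph, m01 / ph
            m10, m11 = m10 * ph, m11 / ph
        eta_prev = ej
    return np.abs(m10 / m00) ** 2


def tmm_reflectance(
    stack: LayerStack, wavelengths, angle_deg: float = 0.0
) -> SimulatedSpectrum:
    """Unpolarised specular reflectance of a layer stack.

    At oblique incidence R is the mean of the s- and p-polarisation
    reflectances; at normal incidence the two coincide.
    """
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    cos0 = np.cos(np.deg2rad(angle_deg))
    R = _tmm_one_pol(
        stack.indices, stack.thicknesses, stack.n_incident, stack.n_substrate,
        wl, cos0, "s",
    )
    if angle_deg != 0.0:
        Rp = _tmm_one_pol(
            stack.indices, stack.thicknesses, stack.n_incident, stack.n_substrate,
            wl, cos0, "p",
        )
        R = 0.5 * (R + Rp)
    hue = float(wl[int(np.argmax(R))])
    return SimulatedSpectrum(wavelengths=wl, reflectance=R, hue_nm=hue)


def simulate_feather_spectrum(
    p: NanostructureParams,
    wavelengths=None,
    angle_deg: float = 0.0,
    slice_thickness: float = 1.0,
    dispersion: DispersionSet = DEFAULT_DISPERSION,
) -> SimulatedSpectrum:
    """Simulate a barbule reflectance spectrum on 300–700 nm at 1 nm (by
    default); hue is the wavelength of maximum reflectance.

    The stack is rebuilt per wavelength so material dispersion enters each
    characteristic matrix with the correct index.
    """
    wl = (
        np.arange(300.0, 701.0, 1.0)
        if wavelengths is None
        else np.atleast_1d(np.asarray(wavelengths, dtype=float))
    )
    cos0 = np.cos(np.deg2rad(angle_deg))
    # geometry is wavelength-independent; only material indices disperse
    n_ker = np.asarray(material_index("keratin", wl, dispersion))
    n_mel = np.asarray(material_index("melanin", wl, dispersion))
    thick, rows = [], []
    for t, kind in _segments(p):
        if kind == "keratin":
            thick.append(t)
            rows.append(n_ker)
        elif kind == "melanin":
            thick.append(t)
            rows.append(n_mel)
        else:
            m = max(1, int(round(t / slice_thickness)))
            edges = np.linspace(-t / 2.0, t / 2.0, m + 1)
            mids = 0.5 * (edges[:-1] + edges[1:])
            frac = np.clip(_air_fraction_profile(p, mids), 0.0, 1.0)
            for dz, f in zip(np.diff(edges), frac):
                thick.append(dz)
                rows.append(f * (1.0 + 0j) + (1.0 - f) * n_mel)
    n_slices = np.vstack(rows) if rows else np.empty((0, wl.size), complex)
    d = np.asarray(thick)
    R = _tmm_one_pol(n_slices, d, 1.0 + 0j, n_ker, wl, cos0, "s")
    if angle_deg != 0.0:
        Rp = _tmm_one_pol(n_slices, d, 1.0 + 0j, n_ker, wl, cos0, "p")
        R = 0.5 * (R + Rp)
    hue = float(wl[int(np.argmax(R))])
    return SimulatedSpectrum(wavelengths=wl, reflectance=R, hue_nm=hue)


def scale_params(p: NanostructureParams, factor: float) -> NanostructureParams:
    """Uniformly scale every length in a parameter set (layer count fixed)."""
    return replace(
        p,
        cortex=p.cortex * factor,
        pt_top=p.pt_top * factor,
        mel=p.mel * factor,
        ker=p.ker * factor,
        air=p.air * factor,
    )


def params_from_means(means, **overrides) -> NanostructureParams:
    """Build a parameter set from a trait-mean mapping or table row with
    keys cortex, pt_top, mel, ker, air, n_layers."""
    get = means.get if hasattr(means, "get") else means.__getitem__
    kwargs = dict(
        cortex=float(get("cortex")), pt_top=float(get("pt_top")),
        mel=float(get("mel")), ker=float(get("ker")), air=float(get("air")),
        n_layers=int(round(float(get("n_layers")))),
    )
    kwargs.update(overrides)
    return NanostructureParams(**kwargs)


def secondary_peak_prominence(
    spectrum, band: tuple[float, float] = (400.0, 500.0), relative: bool = True
) -> float:
    """Largest local-peak prominence inside a wavelength band.

    ``relative`` scales prominence by the spectrum's maximum so that spectra
    of different overall brightness compare fairly. Returns 0 when the band
    holds no local maximum.
    """
    from scipy.signal import find_peaks

    wl = np.asarray(spectrum.wavelengths, dtype=float)
    R = np.asarray(spectrum.reflectance, dtype=float)
    peaks, props = find_peaks(R, prominence=0)
    lo, hi = band
    prom = [
        props["prominences"][j]
        for j, i in enumerate(peaks)
        if lo <= wl[i] <= hi
    ]
    if not prom:
        return 0.0
    out = float(max(prom))
    return out / float(R.max()) if relative else out


def compare_model_to_empirical(simulated, empirical) -> float:
    """Mean hue offset (nm): simulated minus empirical, paired in order."""
    sim = list(simulated)
    emp = list(empirical)
    if not sim or not emp or len(sim) != len(emp):
        raise ValueError("need equal, non-empty simulated and empirical sets")
    from .colour_vision import hue_peak

    offsets = []
    for s, e in zip(sim, emp):
        sim_hue = s.hue_nm if isinstance(s, SimulatedSpectrum) else hue_peak(s)
        emp_hue = e.hue_nm if isinstance(e, SimulatedSpectrum) else hue_peak(e)
        offsets.append(sim_hue - emp_hue)
    return float(np.mean(offsets))
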