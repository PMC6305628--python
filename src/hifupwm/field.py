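"""Per-harmonic focal pressure fields of a focused-bowl transducer.

The drive spectrum is mapped to per-harmonic surface pressure amplitudes
through the transducer's transfer function (a 50-order FIR low-pass that
rejects harmonic orders >= 4), calibrated to a target surface acoustic
power, and propagated with a linear per-harmonic model: the lossless
axisymmetric Rayleigh integral of the uniformly vibrating spherical cap,
with a separable power-law attenuation factor accumulated along the beam
axis through the layered medium.  Nonlinear harmonic generation is outside
this model; harmonics exist in the field only where the drive puts them.

The Rayleigh integral is evaluated by its exact spherical-harmonic
expansion about the centre of curvature,

    p(r_p, mu) = omega rho u0 k R^2 | sum_n (2n+1) I_n j_n(k r_<)
                                      h_n(k r_>) P_n(mu) |,

with I_n the Legendre integral over the cap and (r_<, r_>) the ordered
pair (r_p, R).  The series is a numerically integrated form of the same
bowl radiation pattern as direct surface quadrature (it agrees with it to
~1e-6) and converges everywhere except on the source sphere itself; the
points nearest the transducer face carry the truncation error, which is
irrelevant for focal-region dosimetry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import signal, special

__all__ = [
    "TransducerModel",
    "Layer",
    "MediumStack",
    "Grid",
    "FieldMap",
    "source_amplitudes",
    "calibrate_power",
    "compute_field",
    "focal_beamwidth",
    "clear_field_cache",
    "NP_PER_DB",
]

NP_PER_DB = np.log(10.0) / 20.0  # 0.1151 Np per dB (amplitude convention)


@dataclass(frozen=True)
class TransducerModel:
    """Focused-bowl HIFU source with a band-limiting transfer function.

    Geometry defaults follow a 64 mm aperture / 63 mm focal length bowl at
    1.1 MHz.  The electrical-to-surface-pressure transfer function is a
    50-order FIR low-pass whose passband covers harmonics 1..3 and whose
    stopband (>= 4 f0) sits at least 40 dB down.
    """

    aperture_diameter: float = 0.064
    focal_length: float = 0.063
    centre_frequency: float = 1.1e6
    fir_order: int = 50

    def __post_init__(self):
        if self.aperture_diameter >= 2 * self.focal_length:
            raise ValueError("aperture must be smaller than twice the focal length")

    @property
    def aperture_radius(self) -> float:
        return self.aperture_diameter / 2

    @property
    def half_angle(self) -> float:
        """Cap half-opening angle seen from the centre of curvature."""
        return float(np.arcsin(self.aperture_radius / self.focal_length))

    @property
    def cap_depth(self) -> float:
        return self.focal_length * (1 - np.cos(self.half_angle))

    @property
    def active_area(self) -> float:
        """Spherical-cap surface area, 2 pi R h."""
        return 2 * np.pi * self.focal_length * self.cap_depth

    @property
    def _fir_design(self):
        # Kaiser window sized for ~50 dB stopband with the transition
        # centred midway between 3 f0 and 4 f0
        fs = 16 * self.centre_frequency
        beta = signal.kaiser_beta(50.0)
        taps = signal.firwin(
            self.fir_order + 1, 3.5 * self.centre_frequency,
            window=("kaiser", beta), fs=fs,
        )
        return taps, fs

    def transfer_at(self, freqs) -> np.ndarray:
        """|H(f)| normalised to unity at the centre frequency."""
        freqs = np.atleast_1d(np.asarray(freqs, float))
        taps, fs = self._fir_design
        def mag(f):
            w = 2 * np.pi * f / fs
            return np.abs(np.exp(-1j * np.outer(w, np.arange(len(taps)))) @ taps)
        return mag(freqs) / mag(np.array([self.centre_frequency]))[0]


@dataclass(frozen=True)
class Layer:
    """Homogeneous acoustic layer with power-law absorption.

    ``absorption_coeff`` is alpha0 in dB/(cm MHz^b); ``absorption_exponent``
    is b, so alpha(f) = alpha0 (f/1 MHz)^b dB/cm.
    """

    name: str
    sound_speed: float
    density: float
    absorption_coeff: float
    absorption_exponent: float
    thickness: float

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")

    def absorption_np_per_m(self, f: float) -> float:
        db_per_cm = self.absorption_coeff * (f / 1e6) ** self.absorption_exponent
        return db_per_cm * 100.0 * NP_PER_DB


def _default_layers() -> tuple:
    # literature chicken-muscle stand-ins; all overridable through config
    return (
        Layer("water", 1482.0, 1000.0, 0.0, 2.0, 0.043),
        Layer("tissue", 1547.0, 1060.0, 0.52, 1.1, 0.045),
    )


@dataclass(frozen=True)
class MediumStack:
    """Ordered layers along the beam axis starting at the transducer face.

    The default stack is a water path followed by a 45 mm tissue layer whose
    front face sits 20 mm before the focus, so the focus lies 20 mm deep in
    tissue.
    """

    layers: tuple = dc_field(default_factory=_default_layers)

    def __post_init__(self):
        if not self.layers:
            raise ValueError("at least one layer required")

    @property
    def c0(self) -> float:
        return self.layers[0].sound_speed

    @property
    def rho0(self) -> float:
        return self.layers[0].density

    @property
    def boundaries(self) -> np.ndarray:
        """Layer interface depths, starting at 0."""
        return np.concatenate(([0.0], np.cumsum([l.thickness for l in self.layers])))

    def layer_at(self, z: float) -> Layer:
        b = self.boundaries
        idx = int(np.clip(np.searchsorted(b, z, side="right") - 1, 0, len(self.layers) - 1))
        return self.layers[idx]

    def check_focus_inside_tissue(self, focal_length: float):
        lay = self.layer_at(focal_length)
        if lay.absorption_coeff == 0:
            raise ValueError(
                f"focus at {focal_length * 1e3:.1f} mm falls in the lossless "
                f"layer {lay.name!r}; it must lie inside the tissue layer"
            )

    def cumulative_attenuation_np(self, f: float, z: np.ndarray) -> np.ndarray:
        """Np of amplitude attenuation accumulated from 0 to each depth z."""
        z = np.asarray(z, float)
        b = self.boundaries
        out = np.zeros_like(z)
        for i, lay in enumerate(self.layers):
            lo, hi = b[i], b[i + 1]
            seg = np.clip(z, lo, hi) - lo
            out += seg * lay.absorption_np_per_m(f)
        # beyond the last layer: extend the last layer's absorption
        tail = np.clip(z - b[-1], 0, None)
        out += tail * self.layers[-1].absorption_np_per_m(f)
        return out

    def absorption_map_np_per_m(self, f: float, z: np.ndarray) -> np.ndarray:
        """Local absorption coefficient alpha(f, z) in Np/m at each depth."""
        z = np.asarray(z, float)
        out = np.empty_like(z)
        for i, zz in enumerate(z):
            out[i] = self.layer_at(float(zz)).absorption_np_per_m(f)
        return out


@dataclass(frozen=True)
class Grid:
    """Axisymmetric cell-centred grid: radial axis r >= 0, beam axis z.

    The stored half-plane of radial extent ``r[-1]`` mirrors to a full
    width of ``2 r[-1]``; the default covers 64 mm x 78 mm at 112 um.
    """

    r: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "r", np.asarray(self.r, float))
        object.__setattr__(self, "z", np.asarray(self.z, float))

    @classmethod
    def regular(cls, spacing: float = 112e-6, r_max: float = 0.032,
                z_max: float = 0.078) -> "Grid":
        nr = int(round(r_max / spacing)) + 1
        nz = int(round(z_max / spacing)) + 1
        return cls(np.arange(nr) * spacing, np.arange(nz) * spacing)

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0]) if len(self.r) > 1 else 0.0

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else 0.0

    @property
    def shape(self):
        return len(self.r), len(self.z)

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.r.tobytes())
        h.update(self.z.tobytes())
        return h.hexdigest()[:16]


@dataclass
class FieldMap:
    """Per-harmonic pressure-magnitude grids |p_h|(r, z) in Pa."""

    grid: Grid
    pressures: dict  # harmonic order -> (nr, nz) array
    fundamental_frequency: float
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        for h, p in self.pressures.items():
            p = np.asarray(p, float)
            if p.shape != self.grid.shape:
                raise ValueError(f"harmonic {h} grid shape mismatch")
            if np.any(p < 0):
                raise ValueError("pressure magnitudes must be non-negative")
            self.pressures[h] = p

    @property
    def harmonics(self):
        return sorted(self.pressures)


# ---------------------------------------------------------------------------
# source spectrum -> surface amplitudes

def source_amplitudes(spectrum, transducer: TransducerModel,
                      k_cal: float = 1.0, n_harmonics: int = 6) -> dict:
    """Per-harmonic surface pressure amplitudes (Pa).

    amplitude_h = |A_h| |H(h f0)| k_cal, with ``k_cal`` a single
    electromechanical volts-to-pascals calibration constant.  The absolute
    scale is normally fixed afterwards by :func:`calibrate_power`.
    """
    orders = np.arange(1, n_harmonics + 1)
    missing = [int(o) for o in orders if o not in set(spectrum.harmonic_orders)]
    if missing:
        raise ValueError(f"spectrum must cover harmonic orders 1..{n_harmonics}; "
                         f"missing {missing}")
    f0 = transducer.centre_frequency
    H = transducer.transfer_at(orders * f0)
    return {
        int(o): float(abs(spectrum.amplitude(int(o))) * H[i] * k_cal)
        for i, o in enumerate(orders)
    }


def calibrate_power(amplitudes: dict, target_acoustic_watts: float,
                    transducer: TransducerModel,
                    media: MediumStack | None = None) -> dict:
    """Scale surface amplitudes so the plane-wave surface power matches the
    target:  sum_h p_h^2 / (2 rho c) * active_area = target.

    Harmonic ratios are preserved exactly.
    """
    if media is None:
        media = MediumStack()
    rho_c = media.rho0 * media.c0
    area = transducer.active_area
    total = sum(p * p for p in amplitudes.values()) / (2 * rho_c) * area
    if total <= 0:
        raise ValueError("all-zero amplitude set cannot be calibrated")
    s = float(np.sqrt(target_acoustic_watts / total))
    return {h: p * s for h, p in amplitudes.items()}


def surface_power(amplitudes: dict, transducer: TransducerModel,
                  media: MediumStack | None = None) -> float:
    """Plane-wave acoustic power (W) of a surface amplitude set."""
    if media is None:
        media = MediumStack()
    rho_c = media.rho0 * media.c0
    return sum(p * p for p in amplitudes.values()) / (2 * rho_c) * transducer.active_area


# ---------------------------------------------------------------------------
# lossless bowl field: spherical-harmonic expansion of the Rayleigh integral

def _legendre_cap_integrals(nmax: int, mu0: float) -> np.ndarray:
    P = np.zeros(nmax + 2)
    P[0], P[1] = 1.0, mu0
    for n in range(1, nmax + 1):
        P[n + 1] = ((2 * n + 1) * mu0 * P[n] - n * P[n - 1]) / (n + 1)
    I = np.zeros(nmax + 1)
    I[0] = 1.0 - mu0
    n = np.arange(1, nmax + 1)
    I[n] = (P[n - 1] - P[n + 1]) / (2 * n + 1)
    return I


def _sph_jn_table(nmax: int, z: np.ndarray) -> np.ndarray:
    """j_n(z) for n = 0..nmax over an array z, by Miller downward recurrence."""
    z = np.asarray(z, float)
    out = np.zeros((nmax + 1, z.size))
    nz = z > 1e-12
    zv = z[nz]
    if zv.size:
        nstart = nmax + 20 + int(np.sqrt(nmax) + 0.5)
        jp = np.zeros_like(zv)
        jc = np.full_like(zv, 1e-280)
        tmp = np.zeros((nmax + 1, zv.size))
        for n in range(nstart, -1, -1):
            jm = (2 * n + 3) / zv * jc - jp
            big = np.abs(jm) > 1e250
            if big.any():
                jm[big] *= 1e-200
                jc[big] *= 1e-200
                tmp[:, big] *= 1e-200
            if n <= nmax:
                tmp[n] = jm
            jp, jc = jc, jm
        out[:, nz] = tmp * (np.sin(zv) / zv / tmp[0])
    out[0, ~nz] = 1.0
    return out


def _bowl_unit_field(k: float, R: float, mu0: float, r: np.ndarray,
                     z: np.ndarray, rho_c: float, nmax: int | None = None,
                     chunk: int = 4000) -> np.ndarray:
    """|p| for unit surface pressure amplitude (u0 = 1/(rho c)) on points
    (r, z); apex of the bowl at z = 0, focus at z = R."""
    r = np.asarray(r, float).ravel()
    z = np.asarray(z, float).ravel()
    kR = k * R
    if nmax is None:
        nmax = int(kR + 12 * kR ** (1 / 3) + 60)
    n = np.arange(nmax + 1)
    I = _legendre_cap_integrals(nmax, mu0)
    jR = special.spherical_jn(n, kR)
    yR = special.spherical_yn(n, kR)
    hR = jR + 1j * yR

    rp = np.sqrt(r**2 + (z - R) ** 2)
    mu = np.where(rp > 0, (R - z) / np.where(rp > 0, rp, 1.0), 1.0)
    out = np.zeros(r.size)
    # unit surface pressure: u0 = 1/(rho c), so omega rho u0 k R^2 = (kR)^2
    pref = (k * R) ** 2

    for lo in range(0, r.size, chunk):
        sl = slice(lo, min(lo + chunk, r.size))
        rp_c, mu_c = rp[sl], mu[sl]
        inside = rp_c <= R
        acc = np.zeros(rp_c.size, complex)
        if inside.any():
            zi = k * rp_c[inside]
            jmat = _sph_jn_table(nmax, zi)
            coeff = (2 * n + 1) * I * hR
            acc[inside] = _accumulate(coeff, jmat, mu_c[inside], nmax)
        outm = ~inside
        if outm.any():
            zo = k * rp_c[outm]
            jmat = _sph_jn_table(nmax, zo)
            ymat = _sph_yn_table(nmax, zo)
            coeff = (2 * n + 1) * I * jR
            acc[outm] = _accumulate(coeff, jmat + 1j * ymat, mu_c[outm], nmax)
        out[sl] = np.abs(pref * acc)
    return out


def _sph_yn_table(nmax: int, z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, float)
    out = np.zeros((nmax + 1, z.size))
    y0 = -np.cos(z) / z
    out[0] = y0
    if nmax >= 1:
        out[1] = -np.cos(z) / z**2 - np.sin(z) / z
        for nn in range(2, nmax + 1):
            out[nn] = (2 * nn - 1) / z * out[nn - 1] - out[nn - 2]
    return out


def _accumulate(coeff: np.ndarray, radial: np.ndarray, mu: np.ndarray,
                nmax: int) -> np.ndarray:
    pm1 = np.ones_like(mu)
    acc = coeff[0] * radial[0] * pm1
    if nmax >= 1:
        pcur = mu.copy()
        acc = acc + coeff[1] * radial[1] * pcur
        for nn in range(2, nmax + 1):
            pnew = ((2 * nn - 1) * mu * pcur - (nn - 1) * pm1) / nn
            acc = acc + coeff[nn] * radial[nn] * pnew
            pm1, pcur = pcur, pnew
    return acc


_UNIT_FIELD_CACHE: dict = {}


def clear_field_cache():
    _UNIT_FIELD_CACHE.clear()


def compute_field(transducer: TransducerModel, media: MediumStack,
                  amplitudes: dict, grid: Grid | None = None,
                  allow_coarse: bool = True) -> FieldMap:
    """Propagate per-harmonic surface amplitudes to the field grid.

    Each harmonic's lossless bowl pattern (computed once per grid and
    cached) is scaled by the surface amplitude and multiplied by the
    cumulative power-law attenuation accumulated along the beam axis.

    Parameters
    ----------
    amplitudes : dict
        Harmonic order -> surface pressure amplitude (Pa).
    grid : Grid, optional
        Defaults to the full 112 um grid.  Grids coarser than a quarter
        wavelength at the highest populated harmonic are rejected unless
        ``allow_coarse`` (scaled-down mode, the default).
    """
    if grid is None:
        grid = Grid.regular()
    R = transducer.focal_length
    if not (grid.z[0] <= R <= grid.z[-1]):
        raise ValueError("focus lies outside the computational grid")
    f0 = transducer.centre_frequency
    c0, rho0 = media.c0, media.rho0
    hmax = max((h for h, p in amplitudes.items() if p > 0), default=1)
    lam_min = c0 / (hmax * f0)
    if max(grid.dr, grid.dz) > lam_min / 4 and not allow_coarse:
        raise ValueError(
            f"grid spacing {max(grid.dr, grid.dz):g} m does not resolve "
            f"lambda/4 = {lam_min / 4:g} m at harmonic {hmax}"
        )
    mu0 = np.cos(transducer.half_angle)
    RR, ZZ = np.meshgrid(grid.r, grid.z, indexing="ij")
    pressures = {}
    for h, amp in sorted(amplitudes.items()):
        if amp == 0:
            pressures[h] = np.zeros(grid.shape)
            continue
        fh = h * f0
        k = 2 * np.pi * fh / c0
        key = (round(k, 6), round(R, 9), round(mu0, 12), grid.digest())
        if key not in _UNIT_FIELD_CACHE:
            unit = _bowl_unit_field(k, R, mu0, RR.ravel(), ZZ.ravel(),
                                    rho0 * c0).reshape(grid.shape)
            _UNIT_FIELD_CACHE[key] = unit
        atten = np.exp(-media.cumulative_attenuation_np(fh, grid.z))
        pressures[h] = _UNIT_FIELD_CACHE[key] * amp * atten[None, :]
    return FieldMap(
        grid=grid,
        pressures=pressures,
        fundamental_frequency=f0,
        metadata={
            "c0": c0,
            "rho0": rho0,
            "focal_length": R,
            "aperture_diameter": transducer.aperture_diameter,
        },
    )


def focal_beamwidth(fmap: FieldMap, harmonic: int = 1,
                    level: str | float = "-6dB") -> float:
    """Lateral full beamwidth (m) at the focal plane.

    ``level`` is either a dB value (pressure re focal peak, e.g. -6.0) or
    the string "fwhm-intensity" for the full width at half-maximum
    intensity (amplitude ratio 1/sqrt(2)), the convention many transducer
    datasheets use.
    """
    if level == "fwhm-intensity":
        ratio = 1.0 / np.sqrt(2.0)
    elif isinstance(level, str):
        ratio = 10 ** (float(level.replace("dB", "")) / 20.0)
    else:
        ratio = 10 ** (float(level) / 20.0)
    grid = fmap.grid
    R = fmap.metadata.get("focal_length", 0.063)
    iz = int(np.argmin(np.abs(grid.z - R)))
    prof = fmap.pressures[harmonic][:, iz]
    peak = prof[0]
    below = np.nonzero(prof <= ratio * peak)[0]
    if below.size == 0:
        raise ValueError("profile never falls below the requested level")
    j = below[0]
    # linear interpolation between samples j-1 and j
    r_half = np.interp(ratio * peak, [prof[j], prof[j - 1]],
                       [grid.r[j], grid.r[j - 1]])
    return float(2 * r_half)
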