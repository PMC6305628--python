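"""Heating, temperature, thermal dose and lesion maps.

Volumetric heat deposition follows the absorbed-power form of Nyborg's
heating rate summed over the first six harmonics,

    Q = sum_h alpha_h p_h^2 / (rho c)          [W/m^3]

which feeds the Pennes bioheat equation

    rho C_p dT/dt = k_t lap(T) - w_b rho_b C_b (T - T_b) + Q

solved with an explicit finite-difference scheme on the axisymmetric
(r, z) grid: flux-conservative in r (exactly energy conserving with
insulated boundaries), symmetric at the axis, insulated (zero-flux) outer
boundaries.  Thermal dose is the cumulative-equivalent-minutes metric

    CEM43 = sum_t R^(43 - T) dt,   R = 0.5 (T >= 43 C), 0.25 (T < 43 C)

and a lesion is the region where CEM43 meets the coagulative-necrosis
threshold (240 equivalent minutes by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import FieldMap, Grid, MediumStack

__all__ = [
    "ThermalProperties",
    "TemperatureHistory",
    "ThermalDoseMap",
    "LesionMetrics",
    "heating_rate",
    "pennes_solve",
    "max_stable_dt",
    "cem43",
    "lesion_metrics",
    "CEM43_THRESHOLD_MIN",
]

#: Default coagulative-necrosis threshold (equivalent minutes at 43 C).
CEM43_THRESHOLD_MIN = 240.0


@dataclass(frozen=True)
class ThermalProperties:
    """Acoustic-thermal tissue parameters (chicken-muscle-like defaults)."""

    density: float = 1060.0            # kg/m^3
    sound_speed: float = 1547.0        # m/s
    specific_heat: float = 3421.0      # J/(kg K)
    conductivity: float = 0.49         # W/(m K)
    perfusion_rate: float = 0.0        # 1/s (ex-vivo-like default)
    blood_temperature: float = 37.0    # deg C
    blood_density: float = 1050.0      # kg/m^3
    blood_specific_heat: float = 3617.0  # J/(kg K)
    absorption_per_harmonic: tuple = ()  # Np/m for h = 1..6, optional

    def __post_init__(self):
        for name in ("density", "sound_speed", "specific_heat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.conductivity < 0:
            raise ValueError("conductivity must be >= 0")
        if self.perfusion_rate < 0:
            raise ValueError("perfusion_rate must be >= 0")

    @property
    def diffusivity(self) -> float:
        return self.conductivity / (self.density * self.specific_heat)


@dataclass
class TemperatureHistory:
    """Temperature frames T(r, z) at uniform intervals ``dt``."""

    times: np.ndarray
    frames: np.ndarray  # (nt, nr, nz), deg C
    grid: Grid

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def peak_temperature(self) -> float:
        return float(self.frames.max())


@dataclass
class ThermalDoseMap:
    """CEM43 map with its lesion mask."""

    grid: Grid
    cem43_min: np.ndarray
    threshold_min: float = CEM43_THRESHOLD_MIN
    metadata: dict = dc_field(default_factory=dict)

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.cem43_min >= self.threshold_min


@dataclass(frozen=True)
class LesionMetrics:
    """Cross-section metrics of the (mirrored) axisymmetric lesion."""

    area_mm2: float
    axial_extent_mm: float
    radial_extent_mm: float
    n_cells: int
    pct_change: float | None = None


def heating_rate(fmap: FieldMap, props: ThermalProperties,
                 media: MediumStack | None = None) -> np.ndarray:
    """Q(r, z) in W/m^3, additive over harmonics.

    If ``media`` is given, the absorption coefficient varies with depth
    through the layer stack (zero in lossless layers); otherwise the
    uniform per-harmonic values in ``props.absorption_per_harmonic`` apply.
    Absorption is taken equal to the power-law attenuation (all attenuated
    energy absorbed locally).
    """
    grid = fmap.grid
    rho_c = props.density * props.sound_speed
    Q = np.zeros(grid.shape)
    for h in fmap.harmonics:
        p = fmap.pressures[h]
        if media is not None:
            alpha = media.absorption_map_np_per_m(
                h * fmap.fundamental_frequency, grid.z)[None, :]
        else:
            if h - 1 >= len(props.absorption_per_harmonic):
                raise ValueError(
                    f"absorption_per_harmonic missing harmonic {h}")
            alpha = props.absorption_per_harmonic[h - 1]
        Q += alpha * p * p / rho_c
    return Q


def max_stable_dt(props: ThermalProperties, grid: Grid) -> float:
    """Stability bound of the explicit scheme (axis cell is the stiffest)."""
    kappa = props.diffusivity
    rate = kappa * (4.0 / grid.dr**2 + 2.0 / grid.dz**2)
    if props.perfusion_rate > 0:
        rate += (props.perfusion_rate * props.blood_density *
                 props.blood_specific_heat / (props.density * props.specific_heat))
    return 1.0 / rate if rate > 0 else np.inf


def pennes_solve(Q: np.ndarray, props: ThermalProperties, grid: Grid,
                 t_on: float = 20.0, t_cool: float = 10.0, T0: float = 37.0,
                 dt: float | None = None, store_every: int = 1,
                 T_init: np.ndarray | None = None) -> TemperatureHistory:
    """Explicit finite-difference solution of the Pennes equation.

    The source ``Q`` is applied for ``t_on`` seconds then switched off for a
    further ``t_cool`` seconds of cooling.  Outer boundaries are insulated;
    the r = 0 axis uses the symmetric 4 (T1 - T0) / dr^2 Laplacian.

    Raises
    ------
    ValueError
        If ``dt`` violates the stability bound (the message names the
        maximum stable step).
    """
    Q = np.asarray(Q, float)
    if Q.shape != grid.shape:
        raise ValueError("Q grid shape mismatch")
    dt_max = max_stable_dt(props, grid)
    if dt is None:
        dt = 0.5 * dt_max if np.isfinite(dt_max) else (t_on + t_cool) / 100.0
    if dt > dt_max:
        raise ValueError(
            f"dt = {dt:g} s is unstable for this grid; maximum stable "
            f"dt = {dt_max:.6g} s"
        )
    n_on = int(round(t_on / dt))
    n_total = n_on + int(round(t_cool / dt))

    rho_cp = props.density * props.specific_heat
    kappa = props.diffusivity
    dr, dz = grid.dr, grid.dz
    r = grid.r
    nr, nz = grid.shape

    # flux-conservative radial operator weights
    r_half_p = r[1:-1] + dr / 2
    r_half_m = r[1:-1] - dr / 2
    inv_r_dr2 = 1.0 / (r[1:-1] * dr * dr)

    w_perf = (props.perfusion_rate * props.blood_density *
              props.blood_specific_heat / rho_cp)
    q_term = Q / rho_cp

    if T_init is not None:
        T = np.array(T_init, float)
        if T.shape != (nr, nz):
            raise ValueError("T_init grid shape mismatch")
    else:
        T = np.full((nr, nz), float(T0))
    frames = [T.copy()]
    times = [0.0]
    lap = np.empty_like(T)
    for step in range(1, n_total + 1):
        # radial part
        lap[0] = 4.0 * (T[1] - T[0]) / dr**2
        lap[1:-1] = (r_half_p[:, None] * (T[2:] - T[1:-1]) -
                     r_half_m[:, None] * (T[1:-1] - T[:-2])) * inv_r_dr2[:, None]
        lap[-1] = (r[-1] - dr / 2) / (r[-1] * dr * dr) * (T[-2] - T[-1])
        # axial part (insulated ends via one-sided differences)
        lap[:, 1:-1] += (T[:, 2:] - 2 * T[:, 1:-1] + T[:, :-2]) / dz**2
        lap[:, 0] += (T[:, 1] - T[:, 0]) / dz**2
        lap[:, -1] += (T[:, -2] - T[:, -1]) / dz**2
        dT = kappa * lap - w_perf * (T - props.blood_temperature)
        if step <= n_on:
            dT = dT + q_term
        T = T + dt * dT
        if step % store_every == 0 or step == n_total:
            frames.append(T.copy())
            times.append(step * dt)
    return TemperatureHistory(times=np.asarray(times), frames=np.asarray(frames),
                              grid=grid)


def cell_volumes(grid: Grid) -> np.ndarray:
    """Cell volumes (m^3) of the axisymmetric grid, consistent with the
    conservative radial scheme: the axis cell is a disc of radius dr/2."""
    dr, dz = grid.dr, grid.dz
    w = grid.r * dr
    w = w.copy()
    w[0] = dr * dr / 8.0
    return 2 * np.pi * np.outer(w, np.full(len(grid.z), dz))


def cem43(history: TemperatureHistory, dt: float | None = None,
          threshold_min: float = CEM43_THRESHOLD_MIN) -> ThermalDoseMap:
    """Cumulative equivalent minutes at 43 C (Sapareto-Dewey R values).

    Integrates with the trapezoidal rule over the stored frames.
    """
    if dt is None:
        dt = history.dt
    frames = history.frames
    if not np.all(np.isfinite(frames)):
        raise ValueError("temperature history contains non-finite values")
    dose = np.zeros(frames.shape[1:])
    rates = np.where(frames >= 43.0, 0.5, 0.25) ** (43.0 - frames)
    # trapezoid over time, in minutes
    dose = (0.5 * (rates[:-1] + rates[1:])).sum(axis=0) * dt / 60.0
    return ThermalDoseMap(
        grid=history.grid, cem43_min=dose, threshold_min=threshold_min,
        metadata={"dt": dt, "n_frames": len(frames)},
    )


def lesion_metrics(dose: ThermalDoseMap, threshold_min: float | None = None,
                   reference: "ThermalDoseMap | float | None" = None) -> LesionMetrics:
    """Cross-section area and extents of the lesion.

    The stored half-plane mirrors about the axis: a cell at r > 0 counts
    2 dr dz of cross-section area, the axis cell dr dz.  ``reference`` (a
    dose map or an area in mm^2) enables the percentage-change output; an
    empty reference lesion is an error in that mode.
    """
    thr = dose.threshold_min if threshold_min is None else threshold_min
    mask = dose.cem43_min >= thr
    grid = dose.grid
    dr_mm, dz_mm = grid.dr * 1e3, grid.dz * 1e3
    weights = np.full(grid.shape[0], 2.0 * dr_mm * dz_mm)
    weights[0] = dr_mm * dz_mm
    area = float((mask * weights[:, None]).sum())
    if mask.any():
        iz = np.nonzero(mask.any(axis=0))[0]
        ir = np.nonzero(mask.any(axis=1))[0]
        axial = (grid.z[iz[-1]] - grid.z[iz[0]]) * 1e3 + dz_mm
        radial = 2 * (grid.r[ir[-1]] * 1e3 + dr_mm / 2)
    else:
        axial = radial = 0.0
    pct = None
    if reference is not None:
        if isinstance(reference, ThermalDoseMap):
            ref_area = lesion_metrics(reference).area_mm2
        else:
            ref_area = float(reference)
        if ref_area <= 0:
            raise ValueError("empty reference lesion: percentage change undefined")
        pct = 100.0 * (area - ref_area) / ref_area
    return LesionMetrics(
        area_mm2=area,
        axial_extent_mm=float(axial),
        radial_extent_mm=float(radial),
        n_cells=int(mask.sum()),
        pct_change=pct,
    )
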