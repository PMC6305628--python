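"""Excitation waveform design and sampling.

Three drive schemes for a five-level HIFU pulser are supported:

``sine``
    Ideal linear-amplifier reference, a sampled sinusoid.
``bilevel``
    Two-level square drive (levels -1/+1).  At 50 % duty it is the classic
    square wave whose odd harmonics fall off as 1/n.
``hrpwm``
    Harmonic-reduction PWM: a quarter-wave-symmetric five-level staircase
    whose switching angles are chosen so that the fundamental matches a
    requested modulation index while selected low-order harmonics are
    nulled by destructive interference.

The switching-angle problem is the classic selective-harmonic-elimination
system: for a staircase with unit steps of sign ``s_k`` at angles
``alpha_k`` in [0, pi/2], the Fourier sine coefficients are

    b_n = (4 V / (n pi)) * sum_k s_k cos(n alpha_k)      (odd n)

so nulling harmonic ``n`` requires ``sum_k s_k cos(n alpha_k) = 0`` and the
fundamental target is ``sum_k s_k cos(alpha_k) = m K`` where ``K`` is the
number of rail steps (2 for the five-level bridge) and ``m`` the modulation
index normalised so that m = 1 is the un-nulled full staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExcitationSpec",
    "AngleSolution",
    "SwitchedWaveform",
    "InfeasibleModulationError",
    "design_switching_angles",
    "synthesize",
    "apodisation_set",
    "TWO_ANGLE_H3_BAND",
]

#: Feasible modulation-index band for the 2-angle solution nulling H3.
#: The two closed-form branches are alpha2 = pi/3 - alpha1 (m in [0.75, sqrt(3)/2])
#: and alpha2 = alpha1 + pi/3 (m in [sqrt(3)/4, 0.75]).
TWO_ANGLE_H3_BAND = (np.sqrt(3.0) / 4.0, np.sqrt(3.0) / 2.0)

_ALLOWED_LEVELS = frozenset((-2, -1, 0, 1, 2))
_MIN_SAMPLES_PER_CYCLE = 32


class InfeasibleModulationError(ValueError):
    """Requested modulation index has no switching-angle solution."""


@dataclass(frozen=True)
class ExcitationSpec:
    """Parameters fully describing one excitation waveform.

    Parameters
    ----------
    scheme : {"sine", "bilevel", "hrpwm"}
    centre_frequency : float
        Drive fundamental f0 in Hz (default 1.1 MHz).
    modulation_index : float
        Fraction of the maximum fundamental, in [0, 1].
    duty_cycle : float
        On-fraction for the bilevel scheme (ignored otherwise).
    n_cycles : int
        Number of fundamental cycles to synthesize.
    sample_rate : float
        Output sample rate in Hz; must be >= 32 * centre_frequency.
    rail_step : float
        Volts per level step, so level +-1 maps to +-rail_step and
        +-2 to +-2*rail_step (equal-step rails).
    """

    scheme: str
    centre_frequency: float = 1.1e6
    modulation_index: float = 0.70
    duty_cycle: float = 0.5
    n_cycles: int = 10
    sample_rate: float = 1.1e6 * 256
    rail_step: float = 30.0
    nulled_harmonics: frozenset = frozenset({3})

    def __post_init__(self):
        if self.scheme not in ("sine", "bilevel", "hrpwm"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.centre_frequency <= 0:
            raise ValueError("centre_frequency must be positive")
        if self.sample_rate < _MIN_SAMPLES_PER_CYCLE * self.centre_frequency:
            raise ValueError(
                "sample_rate must be at least "
                f"{_MIN_SAMPLES_PER_CYCLE} x centre_frequency "
                f"(got {self.sample_rate / self.centre_frequency:.1f} samples/cycle)"
            )
        if not 0.0 <= self.modulation_index <= 1.0:
            raise ValueError("modulation_index must lie in [0, 1]")
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.rail_step <= 0:
            raise ValueError("rail_step must be positive")

    @property
    def samples_per_cycle(self) -> float:
        return self.sample_rate / self.centre_frequency

    @property
    def n_samples(self) -> int:
        return int(round(self.n_cycles * self.sample_rate / self.centre_frequency))


@dataclass(frozen=True)
class AngleSolution:
    """Switching angles for one quarter cycle of the HRPWM staircase.

    ``angles[k]`` is where the level changes by ``step_signs[k]`` (unit rail
    steps).  Angles are non-decreasing in [0, pi/2]; a repeated angle is a
    degenerate double step (the two transitions coincide).
    """

    angles: np.ndarray
    step_signs: np.ndarray
    n_pulses_per_half_cycle: int
    modulation_index: float
    nulled_harmonics: frozenset
    residual_fundamental: float
    residual_harmonics: dict

    def fourier_coefficient(self, n: int) -> float:
        """b_n per unit rail step: (4/(n pi)) sum_k s_k cos(n alpha_k)."""
        return 4.0 / (n * np.pi) * float(
            np.sum(self.step_signs * np.cos(n * self.angles))
        )

    @property
    def fundamental_per_rail_step(self) -> float:
        return self.fourier_coefficient(1)


@dataclass
class SwitchedWaveform:
    """Sampled multilevel drive signal.

    ``levels`` holds integer levels in {-2..2} for the switched schemes and
    continuous values (in units of rail_step) for the sine reference.
    """

    sample_rate: float
    levels: np.ndarray
    rail_step: float
    centre_frequency: float
    scheme: str = "hrpwm"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.levels = np.asarray(self.levels)
        if self.scheme != "sine":
            bad = set(np.unique(self.levels)) - _ALLOWED_LEVELS
            if bad:
                raise ValueError(f"levels outside allowed set {{-2..2}}: {sorted(bad)}")
            if np.max(np.abs(self.levels)) > 2:
                raise ValueError("levels exceed +-2")

    @property
    def samples_volts(self) -> np.ndarray:
        return self.levels * self.rail_step

    @property
    def n_samples(self) -> int:
        return len(self.levels)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def n_cycles(self) -> float:
        return self.n_samples * self.centre_frequency / self.sample_rate


def _she_equations(nulled: Sequence[int]):
    """Harmonic orders constrained by the SHE system: fundamental + nulled set."""
    return [1] + sorted(nulled)


def _newton_solve(target_sum: float, signs: np.ndarray, orders: Sequence[int],
                  tol: float = 1e-9, max_iter: int = 100):
    """Solve sum_k s_k cos(n a_k) = target (n=1) / 0 (nulled n) by damped Newton.

    Eight deterministic evenly spaced multi-starts; returns the first converged
    solution with ordered angles in [0, pi/2], else None.
    """
    k = len(signs)
    orders = np.asarray(orders, float)
    rhs = np.zeros(len(orders))
    rhs[0] = target_sum

    def fun(a):
        return np.cos(np.outer(orders, a)) @ signs - rhs

    def jac(a):
        return -np.sin(np.outer(orders, a)) * orders[:, None] * signs[None, :]

    for start in range(8):
        frac = (np.arange(k) + 0.5 + start / 8.0) / (k + 1.0)
        a = np.sort(frac * (np.pi / 2))
        ok = False
        for _ in range(max_iter):
            f = fun(a)
            if np.max(np.abs(f)) < tol:
                ok = True
                break
            J = jac(a)
            # extra angles beyond the constraint count: solve in least-squares sense
            try:
                if J.shape[0] == J.shape[1]:
                    step = np.linalg.solve(J, f)
                else:
                    step = np.linalg.lstsq(J, f, rcond=None)[0]
            except np.linalg.LinAlgError:
                break
            step = np.clip(step, -0.5, 0.5)
            a = a - step
            a = np.clip(a, 0.0, np.pi / 2)
        if not ok:
            continue
        a = np.where(a < 1e-12, 0.0, a)
        if np.all(np.diff(a) >= -1e-10):
            return np.maximum.accumulate(a)
    return None


def design_switching_angles(modulation_index: float,
                            nulled_harmonics=frozenset({3}),
                            tol: float = 1e-9) -> AngleSolution:
    """Design quarter-wave staircase switching angles.

    For ``nulled_harmonics == {3}`` the primary solution uses two rising
    steps (one pulse per half cycle), feasible for m in
    [sqrt(3)/4, sqrt(3)/2] ~ [0.433, 0.866].  Below that band the solver
    escalates to four angles with alternating step signs (two pulses per
    half cycle, peaking at level 1) and additionally nulls harmonics 5 and
    7 to close the system.  Above the band no five-level solution nulling
    H3 exists and :class:`InfeasibleModulationError` is raised.

    Parameters
    ----------
    modulation_index : float
        Target fundamental as a fraction of the full un-nulled staircase.
    nulled_harmonics : set of int
        Subset of {3, 5}.

    Returns
    -------
    AngleSolution
    """
    m = float(modulation_index)
    nulled = frozenset(int(n) for n in nulled_harmonics)
    if not nulled <= {3, 5}:
        raise ValueError("nulled_harmonics must be a subset of {3, 5}")
    if not 0.0 <= m <= 1.0:
        raise ValueError("modulation_index must lie in [0, 1]")
    K = 2  # rail steps of the five-level bridge

    candidates = []
    if nulled in (frozenset({3}), frozenset({5})):
        lo, hi = TWO_ANGLE_H3_BAND
        if lo - 1e-12 <= m <= hi + 1e-12:
            candidates.append((np.array([1.0, 1.0]), _she_equations(nulled), 1))
        elif m < lo:
            candidates.append(
                (np.array([1.0, -1.0, 1.0, -1.0]), _she_equations({3, 5, 7}), 2)
            )
        else:
            # attempt 2-pulse staircase patterns that still peak at level 2
            candidates.append(
                (np.array([1.0, 1.0, -1.0, 1.0]), _she_equations({3, 5, 7}), 2)
            )
            candidates.append(
                (np.array([1.0, -1.0, 1.0, 1.0]), _she_equations({3, 5, 7}), 2)
            )
    elif nulled == frozenset({3, 5}):
        candidates.append(
            (np.array([1.0, 1.0, -1.0, 1.0]), _she_equations({3, 5, 7}), 2)
        )
        candidates.append(
            (np.array([1.0, -1.0, 1.0, 1.0]), _she_equations({3, 5, 7}), 2)
        )
        candidates.append(
            (np.array([1.0, -1.0, 1.0, -1.0]), _she_equations({3, 5, 7}), 2)
        )
    else:  # empty nulled set: symmetric staircase, closed form
        a = float(np.arccos(np.clip(m, 0.0, 1.0)))
        angles = np.array([a, a])
        signs = np.array([1.0, 1.0])
        return _finalize(angles, signs, 1, m, nulled, tol)

    for signs, orders, pulses in candidates:
        a = _newton_solve(m * K, signs, orders, tol=tol)
        if a is not None and _levels_valid(signs):
            return _finalize(a, signs, pulses, m, nulled, tol)

    lo, hi = TWO_ANGLE_H3_BAND
    raise InfeasibleModulationError(
        f"modulation index {m:.4f} is infeasible for nulled set "
        f"{sorted(nulled)}: the one-pulse five-level solution exists for "
        f"m in [{lo:.4f}, {hi:.4f}] and the two-pulse escalation did not "
        "converge"
    )


def _levels_valid(signs: np.ndarray) -> bool:
    run = np.cumsum(signs)
    return bool(np.all(run >= -1e-9) and np.all(run <= 2 + 1e-9))


def _finalize(angles, signs, pulses, m, nulled, tol) -> AngleSolution:
    res_fund = abs(np.sum(signs * np.cos(angles)) - 2 * m)
    fund = abs(np.sum(signs * np.cos(angles)))
    res_h = {}
    for n in sorted(nulled):
        num = abs(np.sum(signs * np.cos(n * angles)))
        res_h[n] = num / max(fund, 1e-300)
    sol = AngleSolution(
        angles=np.asarray(angles, float),
        step_signs=np.asarray(signs, float),
        n_pulses_per_half_cycle=pulses,
        modulation_index=m,
        nulled_harmonics=nulled,
        residual_fundamental=float(res_fund),
        residual_harmonics=res_h,
    )
    if res_fund > 10 * max(tol, 1e-9) or any(v > 1e-6 for v in res_h.values()):
        raise InfeasibleModulationError(
            f"solver returned a non-converged solution for m={m}: "
            f"residual_fundamental={res_fund:.3e}, residual_harmonics={res_h}"
        )
    return sol


def _quantize_index(t: np.ndarray, sample_rate: float) -> np.ndarray:
    """Nearest-sample index of instants ``t``; exact midpoints go to the
    earlier sample (deterministic tie-break)."""
    return np.ceil(t * sample_rate - 0.5).astype(np.int64)


def _staircase_events(solution: AngleSolution):
    """Per-period (phase, level-delta) events of the quarter-wave staircase."""
    a = solution.angles
    s = solution.step_signs.astype(int)
    ev = []
    ev += [(float(ak), int(sk)) for ak, sk in zip(a, s)]
    ev += [(float(np.pi - ak), -int(sk)) for ak, sk in zip(a[::-1], s[::-1])]
    ev += [(float(np.pi + ak), -int(sk)) for ak, sk in zip(a, s)]
    ev += [(float(2 * np.pi - ak), int(sk)) for ak, sk in zip(a[::-1], s[::-1])]
    return ev


def synthesize(spec: ExcitationSpec,
               solution: AngleSolution | None = None) -> SwitchedWaveform:
    """Sample the excitation described by ``spec``.

    Switching instants are quantized to the nearest sample (ties to the
    earlier sample).  HRPWM waveforms are quarter-wave symmetric before
    quantization; bilevel (at 50 % duty) and HRPWM are half-wave
    antisymmetric.
    """
    n = spec.n_samples
    f0 = spec.centre_frequency
    fs = spec.sample_rate
    period = 1.0 / f0

    if spec.scheme == "sine":
        t = np.arange(n) / fs
        levels = 2.0 * spec.modulation_index * np.sin(2 * np.pi * f0 * t)
        meta = {"modulation_index": spec.modulation_index}
    else:
        deltas = np.zeros(n + 1, dtype=np.int64)
        if spec.scheme == "bilevel":
            events = [(0.0, +2), (spec.duty_cycle * 2 * np.pi, -2)]
            # start the record at level +1: the +2 delta at phase 0 acts on a
            # baseline of -1
            base = -1
            meta = {"duty_cycle": spec.duty_cycle}
        else:
            if solution is None:
                solution = design_switching_angles(
                    spec.modulation_index, spec.nulled_harmonics
                )
            events = _staircase_events(solution)
            base = 0
            meta = {
                "modulation_index": spec.modulation_index,
                "angles_rad": [float(x) for x in solution.angles],
                "step_signs": [int(x) for x in solution.step_signs],
                "nulled_harmonics": sorted(solution.nulled_harmonics),
            }
        for cyc in range(spec.n_cycles):
            t_cyc = cyc * period
            for phase, dlev in events:
                idx = _quantize_index(
                    np.array([t_cyc + phase / (2 * np.pi) * period]), fs
                )[0]
                if 0 <= idx < n:
                    deltas[idx] += dlev
        levels = base + np.cumsum(deltas[:n])
        if np.max(np.abs(levels)) > 2:
            raise RuntimeError("quantization produced an out-of-range level")
    meta["scheme"] = spec.scheme
    return SwitchedWaveform(
        sample_rate=fs,
        levels=levels,
        rail_step=spec.rail_step,
        centre_frequency=f0,
        scheme=spec.scheme,
        metadata=meta,
    )


def measured_fundamental(waveform: SwitchedWaveform) -> float:
    """|fundamental| of the sampled record in volts, by direct projection
    over the full (integer-cycle) record."""
    x = waveform.samples_volts
    n = len(x)
    cycles = waveform.n_cycles
    if abs(cycles - round(cycles)) > 1e-6:
        raise ValueError("record does not span an integer number of cycles")
    kbin = int(round(cycles))
    ph = np.exp(-2j * np.pi * kbin * np.arange(n) / n)
    return float(2.0 * abs(np.dot(x, ph)) / n)


def apodisation_set(m_values: Sequence[float],
                    spec: ExcitationSpec | None = None) -> list[SwitchedWaveform]:
    """Synthesize one HRPWM waveform per modulation index at fixed rails.

    All infeasible entries are reported together; the measured fundamental
    is checked to increase with m for strictly increasing inputs.
    """
    if spec is None:
        spec = ExcitationSpec(scheme="hrpwm")
    bad = []
    sols = []
    for m in m_values:
        try:
            sols.append(design_switching_angles(m, spec.nulled_harmonics))
        except (InfeasibleModulationError, ValueError):
            bad.append(m)
    if bad:
        raise InfeasibleModulationError(
            f"infeasible modulation indices: {bad}"
        )
    out = []
    for m, sol in zip(m_values, sols):
        s = ExcitationSpec(
            scheme="hrpwm",
            centre_frequency=spec.centre_frequency,
            modulation_index=float(m),
            duty_cycle=spec.duty_cycle,
            n_cycles=spec.n_cycles,
            sample_rate=spec.sample_rate,
            rail_step=spec.rail_step,
            nulled_harmonics=spec.nulled_harmonics,
        )
        out.append(synthesize(s, sol))
    return out
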