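"""True electrical power from aligned voltage/current records.

The delivered real power density is computed spectrally,

    P(f) = Re( V(f) I(f)* ),

and the total delivered power over a measurement band [f_lo, f_hi] is the
integral of P(f).  The one-sided density normalization is fixed by a
Parseval contract: integrating the density over the full band reproduces
the time-domain mean of v(t) i(t) exactly (for even-length records).  The
default band is the 500 kHz - 10 MHz window used for switched-drive power
measurements.

Records are not windowed: the intended use is synchronous multi-cycle
captures (e.g. 100-cycle excitations) where all tones sit on DFT bins;
band-edge leakage on asynchronous records is the caller's risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VITrace",
    "PowerSpectrum",
    "power_spectrum",
    "total_true_power",
    "DEFAULT_BAND",
]

#: Measurement band (Hz) for switched-drive true-power totals.
DEFAULT_BAND = (500e3, 10e6)


@dataclass(frozen=True)
class VITrace:
    """Aligned sampled voltage and current (same time base)."""

    sample_interval: float
    voltage: np.ndarray
    current: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.voltage, float)
        i = np.asarray(self.current, float)
        if v.shape != i.shape or v.ndim != 1:
            raise ValueError("voltage and current must be equal-length 1-D arrays")
        if len(v) < 2:
            raise ValueError("need at least 2 samples")
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(i))):
            raise ValueError("voltage/current contain non-finite values")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        object.__setattr__(self, "voltage", v)
        object.__setattr__(self, "current", i)

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.sample_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.voltage)) * self.sample_interval

    def mean_instantaneous_power(self) -> float:
        """Time-domain mean of v*i in watts (the Parseval reference)."""
        return float(np.mean(self.voltage * self.current))


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided true-power density (signed, W/Hz) on a uniform grid."""

    frequencies: np.ndarray
    true_power_density: np.ndarray

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def band_integral(self, f_lo: float, f_hi: float) -> float:
        """Trapezoidal integral of the density over [f_lo, f_hi] (watts)."""
        f = self.frequencies
        if f_lo >= f_hi:
            raise ValueError("f_lo must be below f_hi")
        if f_lo < f[0] - 1e-9 or f_hi > f[-1] + 1e-9:
            raise ValueError(
                f"band [{f_lo:g}, {f_hi:g}] Hz outside spectrum support "
                f"[{f[0]:g}, {f[-1]:g}] Hz"
            )
        f_lo = max(f_lo, f[0])
        f_hi = min(f_hi, f[-1])
        inner = (f > f_lo) & (f < f_hi)
        grid = np.concatenate(([f_lo], f[inner], [f_hi]))
        dens = np.concatenate((
            [np.interp(f_lo, f, self.true_power_density)],
            self.true_power_density[inner],
            [np.interp(f_hi, f, self.true_power_density)],
        ))
        return float(np.trapezoid(dens, grid))


def power_spectrum(trace: VITrace) -> PowerSpectrum:
    """True-power density Re(V I*) of an aligned voltage/current record.

    The density carries a factor 2/df at every bin (including DC and the
    Nyquist bin) so that the trapezoidal full-band integral telescopes to
    the exact two-sided Parseval sum, i.e. to ``mean(v * i)``.
    """
    v = trace.voltage
    i = trace.current
    n = len(v)
    V = np.fft.rfft(v) / n
    I = np.fft.rfft(i) / n
    cross = np.real(V * np.conj(I))
    df = trace.sample_rate / n
    freqs = np.fft.rfftfreq(n, trace.sample_interval)
    density = 2.0 * cross / df
    return PowerSpectrum(frequencies=freqs, true_power_density=density)


def total_true_power(spectrum: PowerSpectrum,
                     f_lo: float = DEFAULT_BAND[0],
                     f_hi: float = DEFAULT_BAND[1]) -> float:
    """Band-integrated delivered true power in watts."""
    return spectrum.band_integral(f_lo, f_hi)
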