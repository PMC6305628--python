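"""Harmonic content of periodic drive waveforms.

All levels are reported in dB relative to the fundamental (the fundamental
is exactly 0 dB).  Amplitudes are taken from a DFT over an exact integer
number of fundamental cycles, so no window is needed and there is no
leakage: a record with a non-integer cycle count is rejected rather than
silently windowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveforms import SwitchedWaveform

__all__ = [
    "HarmonicSpectrum",
    "harmonic_levels",
    "harmonic_levels_from_samples",
    "suppression_check",
    "NUMERICAL_FLOOR_DB",
]

#: Declared numerical floor: content at or below this is "absent".
NUMERICAL_FLOOR_DB = -80.0


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Complex amplitudes at integer harmonics of the fundamental."""

    fundamental_frequency: float
    harmonic_orders: np.ndarray
    complex_amplitudes: np.ndarray

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.complex_amplitudes)

    @property
    def levels_db(self) -> np.ndarray:
        """20 log10(|A_n| / |A_1|); the fundamental entry is exactly 0."""
        mags = self.magnitudes
        a1 = mags[self.harmonic_orders == 1]
        if a1.size == 0 or a1[0] == 0:
            raise ValueError("spectrum has no fundamental amplitude")
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(mags / a1[0])
        db[self.harmonic_orders == 1] = 0.0
        return db

    def level_db(self, order: int) -> float:
        idx = np.nonzero(self.harmonic_orders == order)[0]
        if idx.size == 0:
            raise KeyError(f"harmonic order {order} not computed")
        return float(self.levels_db[idx[0]])

    def amplitude(self, order: int) -> complex:
        idx = np.nonzero(self.harmonic_orders == order)[0]
        if idx.size == 0:
            raise KeyError(f"harmonic order {order} not computed")
        return complex(self.complex_amplitudes[idx[0]])


def harmonic_levels_from_samples(x: np.ndarray, sample_rate: float,
                                 fundamental: float,
                                 n_harmonics: int = 6) -> HarmonicSpectrum:
    """Harmonic amplitudes of a sampled record spanning integer cycles.

    The complex amplitude of harmonic ``n`` is ``2 X[n*c] / N`` where ``c``
    is the cycle count, i.e. the peak amplitude of the corresponding
    sinusoid.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2:
        raise ValueError("record too short")
    cycles = n * fundamental / sample_rate
    if cycles < 1 - 1e-9:
        raise ValueError("record must span at least one full cycle")
    if abs(cycles - round(cycles)) > 1e-6 * max(1.0, cycles):
        raise ValueError(
            f"record spans {cycles:.6f} cycles; an integer cycle count is "
            "required (spectral leakage would corrupt the dB levels)"
        )
    cyc = int(round(cycles))
    if n_harmonics * fundamental >= sample_rate / 2:
        raise ValueError("n_harmonics * fundamental must be below Nyquist")
    X = np.fft.rfft(x)
    orders = np.arange(1, n_harmonics + 1)
    bins = orders * cyc
    amps = 2.0 * X[bins] / n
    return HarmonicSpectrum(
        fundamental_frequency=fundamental,
        harmonic_orders=orders,
        complex_amplitudes=amps,
    )


def harmonic_levels(waveform: SwitchedWaveform,
                    n_harmonics: int = 6) -> HarmonicSpectrum:
    """Harmonic spectrum of a synthesized drive waveform (volts)."""
    return harmonic_levels_from_samples(
        waveform.samples_volts,
        waveform.sample_rate,
        waveform.centre_frequency,
        n_harmonics,
    )


def suppression_check(spectrum: HarmonicSpectrum, band_orders,
                      floor_db: float = 20.0):
    """Check that each listed harmonic sits at least ``floor_db`` below the
    fundamental.

    Returns ``(ok, worst_order, worst_level_db)``; an empty order set is
    vacuously true with ``(True, None, None)``.
    """
    orders = sorted(int(o) for o in band_orders)
    if not orders:
        return True, None, None
    missing = [o for o in orders if o not in set(spectrum.harmonic_orders)]
    if missing:
        raise KeyError(f"harmonic orders not in spectrum: {missing}")
    levels = np.array([spectrum.level_db(o) for o in orders])
    worst = int(np.argmax(levels))
    ok = bool(np.all(levels <= -floor_db))
    return ok, orders[worst], float(levels[worst])
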