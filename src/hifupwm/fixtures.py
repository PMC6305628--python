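"""Seeded synthetic-signal generation.

These generators stand in for laboratory hardware so that every analysis
path can be exercised deterministically: a lumped electrical load model
(series R-L with a parallel shunt capacitance, a transducer-like stand-in
with unknown switched-source output impedance) produces aligned
voltage/current records from any drive waveform, and a burst generator
produces PCD traces with injected broadband/ultraharmonic events.  All
randomness is drawn from ``numpy.random.default_rng(seed)``: regenerating
with the same seed and parameters is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .pcd import PCDRecording
from .power import VITrace
from .waveforms import SwitchedWaveform

__all__ = ["LoadModel", "BurstSpec", "make_vi_trace", "make_pcd_trace"]


@dataclass(frozen=True)
class LoadModel:
    """Series R-L branch with a parallel shunt capacitance across the input."""

    resistance: float = 50.0      # ohm
    inductance: float = 0.0       # henry
    capacitance: float = 0.0      # farad

    def __post_init__(self):
        if min(self.resistance, self.inductance, self.capacitance) < 0:
            raise ValueError("load elements must be non-negative")
        if self.resistance == 0 and self.inductance == 0 and self.capacitance == 0:
            raise ValueError("degenerate all-zero load")

    def admittance(self, f) -> np.ndarray:
        """Complex input admittance at frequencies ``f`` (Hz).

        The DC bin of a pure-reactance load is treated as open (zero
        admittance): the records this model feeds carry no DC drive.
        """
        f = np.atleast_1d(np.asarray(f, float))
        w = 2 * np.pi * f
        z_series = self.resistance + 1j * w * self.inductance
        y = np.zeros_like(w, complex)
        nonzero = np.abs(z_series) > 0
        y[nonzero] = 1.0 / z_series[nonzero]
        y += 1j * w * self.capacitance
        return y

    def impedance(self, f) -> np.ndarray:
        y = self.admittance(f)
        with np.errstate(divide="ignore"):
            return np.where(np.abs(y) > 0, 1.0 / y, np.inf)


def make_vi_trace(waveform: SwitchedWaveform, load: LoadModel,
                  noise_rms: float = 0.0, seed: int | None = None) -> VITrace:
    """Drive the lumped load with a waveform; current is computed
    per-frequency from the load admittance (exact linear phasor response).
    """
    v = np.asarray(waveform.samples_volts, float)
    n = len(v)
    freqs = np.fft.rfftfreq(n, 1.0 / waveform.sample_rate)
    V = np.fft.rfft(v)
    I = V * load.admittance(freqs)
    i = np.fft.irfft(I, n)
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_rms, n)
        i = i + rng.normal(0.0, noise_rms, n)
    return VITrace(sample_interval=1.0 / waveform.sample_rate,
                   voltage=v, current=i)


@dataclass(frozen=True)
class BurstSpec:
    """Shape of one injected cavitation-like burst."""

    duration: float = 20e-6       # s
    amplitude: float = 1.0        # V, broadband component peak
    tones: tuple = ()             # ((freq_hz, amplitude_v), ...)
    broadband: bool = True


def make_pcd_trace(event_times, burst_spec: BurstSpec | None = None,
                   noise_rms: float = 0.05, seed: int = 0,
                   duration: float | None = None,
                   sample_rate: float = 62.5e6,
                   trigger_threshold: float = 0.380,
                   holdoff: float = 0.050) -> PCDRecording:
    """Gaussian background noise plus band-limited bursts at given times.

    Each burst is a Hann-windowed packet of broadband noise and/or discrete
    tones (e.g. an 11.55 MHz ultraharmonic line).  Event times must be
    sorted ascending.
    """
    event_times = np.asarray(list(event_times), float)
    if event_times.size and np.any(np.diff(event_times) < 0):
        raise ValueError("event times must be sorted ascending")
    if burst_spec is None:
        burst_spec = BurstSpec()
    if duration is None:
        tail = burst_spec.duration + 300e-6
        duration = (event_times[-1] + tail) if event_times.size else 1e-3
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    x = rng.normal(0.0, noise_rms, n) if noise_rms > 0 else np.zeros(n)
    bn = int(round(burst_spec.duration * sample_rate))
    win = np.hanning(bn)
    t_b = np.arange(bn) / sample_rate
    for t0 in event_times:
        i0 = int(round(t0 * sample_rate))
        if i0 >= n:
            continue
        burst = np.zeros(bn)
        if burst_spec.broadband:
            burst += burst_spec.amplitude * rng.normal(0.0, 1.0, bn)
        for f_tone, a_tone in burst_spec.tones:
            burst += a_tone * np.sin(2 * np.pi * f_tone * t_b)
        seg = slice(i0, min(i0 + bn, n))
        x[seg] += (burst * win)[: seg.stop - seg.start]
    return PCDRecording(
        sample_rate=sample_rate,
        trace=x,
        trigger_threshold=trigger_threshold,
        holdoff=holdoff,
        metadata={"seed": seed, "noise_rms": noise_rms,
                  "event_times": event_times.tolist()},
    )
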