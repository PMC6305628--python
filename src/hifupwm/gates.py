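"""Compile five-level waveforms into bridge gate-control schedules.

The pulser bridge exposes six MOSFET gates: active-low ``nA2p``, ``nA1p``
(positive rails) and ``nA0p`` (clamp pMOS), and active-high ``A0n`` (clamp
nMOS), ``A1n``, ``A2n`` (negative rails).  Level-to-path mapping:

    +2 -> nA2p      +1 -> nA1p      0 -> clamp (nA0p + A0n together)
    -1 -> A1n       -2 -> A2n

Internally every trace is stored as a logical "device conducting" boolean;
the exported 0/1 table applies the electrical polarity (a conducting
active-low gate exports 0).

Two hardware constraints are enforced: a dead-time gap of all-off samples
between any two distinct conducting paths (shoot-through prevention), and
an on-time limit on the four level-shifted rail gates, whose capacitive
level shifters droop if held on (about 1 ms); the clamp pair is exempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveforms import SwitchedWaveform

__all__ = [
    "GateSchedule",
    "GateViolation",
    "OnTimeError",
    "compile_gates",
    "decompile_gates",
    "validate",
    "GATE_NAMES",
    "RAIL_GATES",
]

GATE_NAMES = ("nA2p", "nA1p", "nA0p", "A0n", "A1n", "A2n")
#: Gates with capacitive level shifters, subject to the on-time limit.
RAIL_GATES = ("nA2p", "nA1p", "A1n", "A2n")
_ACTIVE_LOW = ("nA2p", "nA1p", "nA0p")

_LEVEL_TO_GATES = {
    2: ("nA2p",),
    1: ("nA1p",),
    0: ("nA0p", "A0n"),
    -1: ("A1n",),
    -2: ("A2n",),
}
_DEAD = -99  # sentinel for dead-time samples in decompiled output


class OnTimeError(ValueError):
    """A level-shifted gate would be held on longer than the hardware allows."""


@dataclass(frozen=True)
class GateViolation:
    sample: int
    rule: str

    def __str__(self):
        return f"sample {self.sample}: {self.rule}"


@dataclass
class GateSchedule:
    """Six conducting-state traces plus dead-time bookkeeping."""

    sample_rate: float
    traces: dict
    dead_time: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.traces) != set(GATE_NAMES):
            raise ValueError(f"traces must be exactly {GATE_NAMES}")
        n = {len(v) for v in self.traces.values()}
        if len(n) != 1:
            raise ValueError("all traces must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.traces[GATE_NAMES[0]])

    def to_table(self) -> np.ndarray:
        """(n_samples, 6) 0/1 electrical levels in GATE_NAMES column order.

        Active-low gates read 0 when conducting.
        """
        cols = []
        for name in GATE_NAMES:
            on = np.asarray(self.traces[name], bool)
            cols.append((~on if name in _ACTIVE_LOW else on).astype(np.uint8))
        return np.column_stack(cols)


def _path_ids(waveform_levels: np.ndarray) -> np.ndarray:
    return np.asarray(waveform_levels, int)


def compile_gates(waveform: SwitchedWaveform, dead_time: float = 100e-9,
                  on_time_limit: float = 1e-3) -> GateSchedule:
    """Compile a switched waveform into the six gate traces.

    The clamp acts as the resting state: at every transition between
    distinct conducting paths a dead gap of ``round(dead_time *
    sample_rate)`` (at least one) all-off samples is carved out.  The gap is
    taken from the clamp side of the transition when one exists (clamp
    released early / engaged late) and from the outgoing run otherwise, so
    the output only floats during dead time.

    Raises
    ------
    OnTimeError
        If a level-shifted rail gate would conduct continuously for longer
        than ``on_time_limit`` (default 1 ms).
    ValueError
        If the dead time is below one sample period.
    """
    if waveform.scheme == "sine":
        raise ValueError("cannot compile a continuous sine waveform to gates")
    fs = waveform.sample_rate
    n_dead = int(round(dead_time * fs))
    if n_dead < 1:
        raise ValueError(
            f"dead_time {dead_time:g} s is below one sample period at "
            f"sample_rate {fs:g} Hz"
        )
    levels = _path_ids(waveform.levels)
    n = len(levels)
    conduct = levels.copy()  # per-sample conducting level; _DEAD marks all-off

    # run boundaries
    change = np.nonzero(np.diff(levels) != 0)[0] + 1
    for b in change:
        prev_level = levels[b - 1]
        next_level = levels[b]
        if next_level == 0:
            sl = slice(b, min(b + n_dead, n))  # clamp engages late
        else:
            sl = slice(max(b - n_dead, 0), b)  # clamp released early / outgoing cut
        conduct[sl] = _DEAD

    traces = {name: np.zeros(n, bool) for name in GATE_NAMES}
    for lev, gates in _LEVEL_TO_GATES.items():
        mask = conduct == lev
        for g in gates:
            traces[g][mask] = True

    sched = GateSchedule(
        sample_rate=fs,
        traces=traces,
        dead_time=n_dead / fs,
        metadata={
            "dead_samples": n_dead,
            "on_time_limit": on_time_limit,
            "scheme": waveform.scheme,
        },
    )
    _check_on_time(sched, on_time_limit, raise_error=True)
    return sched


def _runs(mask: np.ndarray):
    """(start, length) of each True run."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, [e - s for s, e in zip(starts, ends)]))


def _check_on_time(schedule: GateSchedule, limit: float, raise_error=False):
    violations = []
    max_run = int(np.floor(limit * schedule.sample_rate))
    for name in RAIL_GATES:
        for start, length in _runs(np.asarray(schedule.traces[name], bool)):
            if length > max_run:
                dur = length / schedule.sample_rate
                if raise_error:
                    raise OnTimeError(
                        f"gate {name} conducts for {dur * 1e3:.3f} ms from "
                        f"sample {start}, exceeding the {limit * 1e3:.1f} ms "
                        "on-time limit"
                    )
                violations.append(GateViolation(start, f"on-time: {name} {dur:.4g} s"))
    return violations


def decompile_gates(schedule: GateSchedule) -> np.ndarray:
    """Recover the level sequence; dead-time (all-off) samples are masked.

    Returns a masked array whose unmasked entries are the conducting level.
    Samples with an inconsistent gate combination raise ValueError.
    """
    n = schedule.n_samples
    out = np.zeros(n, int)
    mask = np.zeros(n, bool)
    tr = {k: np.asarray(v, bool) for k, v in schedule.traces.items()}
    any_on = np.zeros(n, bool)
    for lev, gates in _LEVEL_TO_GATES.items():
        on = np.logical_and.reduce([tr[g] for g in gates])
        out[on] = lev
        any_on |= on
    mask[~any_on] = True
    # clamp half-engaged counts as undefined output
    half = (tr["nA0p"] ^ tr["A0n"])
    mask[half] = True
    return np.ma.masked_array(out, mask=mask)


def validate(schedule: GateSchedule, on_time_limit: float | None = None) -> list:
    """Check mutual exclusion, dead-time, and on-time invariants.

    Returns a list of :class:`GateViolation`; empty iff the schedule is
    valid.
    """
    tr = {k: np.asarray(v, bool) for k, v in schedule.traces.items()}
    n = schedule.n_samples
    violations = []

    # conducting paths per sample: each rail gate is its own path; either
    # clamp device presents a path through ground
    rail_paths = np.column_stack([tr[g] for g in RAIL_GATES])
    clamp_path = tr["nA0p"] | tr["A0n"]
    n_paths = rail_paths.sum(axis=1) + clamp_path.astype(int)
    for idx in np.nonzero(n_paths > 1)[0]:
        on = [g for g in RAIL_GATES if tr[g][idx]]
        if clamp_path[idx]:
            on.append("clamp")
        violations.append(GateViolation(int(idx), f"shoot-through: {'+'.join(on)}"))

    # dead-time between distinct paths
    n_dead = int(round(schedule.dead_time * schedule.sample_rate))
    path_id = np.full(n, -1, int)
    for j, g in enumerate(RAIL_GATES):
        path_id[tr[g]] = j
    path_id[clamp_path] = 4
    active = path_id >= 0
    idx_active = np.nonzero(active)[0]
    if idx_active.size:
        ids = path_id[idx_active]
        switch = np.nonzero(np.diff(ids) != 0)[0]
        for s in switch:
            gap = idx_active[s + 1] - idx_active[s] - 1
            if gap < n_dead:
                violations.append(
                    GateViolation(
                        int(idx_active[s + 1]),
                        f"dead-time: {gap} off samples between paths, "
                        f"{n_dead} required",
                    )
                )

    limit = on_time_limit
    if limit is None:
        limit = schedule.metadata.get("on_time_limit", 1e-3)
    violations.extend(_check_on_time(schedule, limit))
    violations.sort(key=lambda v: v.sample)
    return violations
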