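"""Single-cell stimulation protocols and biomarkers.

Pacing follows the study conditions: square current pulses of -52 pA/pF for
1 ms at a basic cycle length (BCL) of 800 ms, with an optional premature S2
of identical shape.  Derived biomarkers:

* APD90 — action-potential duration from the instant of maximum dV/dt to
  90% repolarization, the amplitude being peak V minus the pre-stimulus V;
  crossings are linearly interpolated between samples.
* ERP — effective refractory period: the shortest S1-S2 coupling interval
  whose S2 response still qualifies as an action potential (a regenerative
  upstroke overshooting 0 mV), located by a coarse 5 ms scan refined by
  bisection to 0.5 ms.
* APD and ERP restitution curves with their maximal (forward
  finite-difference) slopes.
* delta-V — pointwise membrane-potential difference between two cell types,
  with its repolarization-phase maximum (the transmural-heterogeneity
  driver of the T wave).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import _kernel
from .errors import (
    AlignmentError,
    DomainError,
    InstabilityError,
    MeasurementError,
    ProtocolError,
)
from .ionic_cell import DT_DEFAULT, CellParams, CellState, resting_state

__all__ = [
    "StimulusProtocol",
    "ApTrace",
    "RestitutionCurve",
    "pace",
    "measure_apd90",
    "measure_erp",
    "restitution",
    "max_slope",
    "delta_v",
]

log = logging.getLogger(__name__)

AP_PEAK_THRESHOLD = 0.0   # mV; an S2 response must overshoot this level
AP_UPSTROKE_DVDT = 20.0   # mV/ms after stimulus end; regenerative criterion


@dataclass(frozen=True)
class StimulusProtocol:
    """S1(-S2) pacing protocol."""

    s1_amplitude: float = -52.0   # pA/pF
    s1_duration: float = 1.0      # ms
    bcl: float = 800.0            # ms
    n_beats: int = 10             # conditioning beats
    s2_coupling: float | None = None  # ms after the last S1 onset

    def __post_init__(self):
        if self.s1_duration <= 0:
            raise DomainError("stimulus duration must be positive")
        if self.bcl <= self.s1_duration:
            raise DomainError("BCL must exceed the stimulus duration")
        if self.n_beats < 0:
            raise DomainError("number of beats must be non-negative")
        if self.s2_coupling is not None and self.s2_coupling < 0:
            raise DomainError("S2 coupling interval must be non-negative")

    def with_s2(self, coupling: float) -> "StimulusProtocol":
        return replace(self, s2_coupling=coupling)


@dataclass
class ApTrace:
    """Uniformly sampled membrane-potential trace."""

    t: np.ndarray            # ms, t[0] = 0 at trace start
    v: np.ndarray            # mV
    stim_onsets: tuple[float, ...]  # ms, within the trace
    dt: float                # sampling interval (= integration dt here)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise AlignmentError("time and voltage arrays differ in length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.t, "V_mV": self.v})


@dataclass(frozen=True)
class RestitutionCurve:
    """APD-R (APD90 vs diastolic interval) or ERP-R (ERP vs BCL)."""

    kind: str                 # "APD-R" | "ERP-R"
    x: np.ndarray             # ms (DI or BCL), strictly increasing
    y: np.ndarray             # ms
    max_slope: float
    excluded: tuple[float, ...] = ()   # abscissa points that failed

    def __post_init__(self):
        if np.any(np.diff(self.x) <= 0):
            raise DomainError("restitution abscissa must be strictly increasing")


def _run_cell(
    state: np.ndarray,
    P: np.ndarray,
    dt: float,
    n_steps: int,
    stim_steps: np.ndarray,
    stim_dur_steps: int,
    stim_amp: float,
    snap_steps: np.ndarray | None = None,
    rush_larsen: bool = True,
):
    v_rec = np.empty(n_steps + 1)
    if snap_steps is None:
        snap_steps = np.empty(0, dtype=np.int64)
    snaps = np.empty((len(snap_steps), _kernel.NSTATE))
    status = _kernel.integrate_cell(
        state, P, dt, n_steps, stim_steps, stim_dur_steps, stim_amp, 1,
        v_rec, snap_steps, snaps, rush_larsen,
    )
    if status >= 0:
        raise InstabilityError(
            f"membrane voltage diverged at t = {status * dt:.2f} ms",
            t_ms=status * dt,
        )
    return v_rec, snaps


def pace(
    p: CellParams,
    proto: StimulusProtocol = StimulusProtocol(),
    dt: float = DT_DEFAULT,
    rush_larsen: bool = True,
) -> ApTrace:
    """Pace from the committed resting state; return the final-beat trace.

    The returned trace starts at the onset of the last conditioning S1 beat
    (or at rest when ``n_beats`` is 0) and, when an S2 is configured,
    extends far enough to contain the full S2 response.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    state = resting_state(p, dt=dt).values.copy()
    P = p.to_array()
    stim_dur_steps = max(1, int(round(proto.s1_duration / dt)))
    if proto.n_beats == 0 and proto.s2_coupling is None:
        n_steps = int(round(proto.bcl / dt))
        v_rec, _ = _run_cell(
            state, P, dt, n_steps, np.empty(0, np.int64), stim_dur_steps,
            proto.s1_amplitude, rush_larsen=rush_larsen,
        )
        t = np.arange(n_steps + 1) * dt
        return ApTrace(t, v_rec, (), dt)

    last_onset = (proto.n_beats - 1) * proto.bcl if proto.n_beats else 0.0
    tail = proto.bcl
    onsets = [i * proto.bcl for i in range(proto.n_beats)]
    s2_time = None
    if proto.s2_coupling is not None:
        s2_time = last_onset + proto.s2_coupling
        tail = max(proto.bcl, proto.s2_coupling + 600.0)
        onsets.append(s2_time)
    total = last_onset + tail
    n_steps = int(round(total / dt))
    stim_steps = np.array(sorted(int(round(o / dt)) for o in onsets), np.int64)
    v_rec, _ = _run_cell(
        state, P, dt, n_steps, stim_steps, stim_dur_steps, proto.s1_amplitude,
        rush_larsen=rush_larsen,
    )
    i0 = int(round(last_onset / dt))
    v = v_rec[i0:]
    t = np.arange(v.size) * dt
    rel_onsets = [0.0]
    if s2_time is not None:
        rel_onsets.append(s2_time - last_onset)
    return ApTrace(t, v, tuple(rel_onsets), dt)


def measure_apd90(trace: ApTrace, stim_index: int = -1) -> float:
    """APD90 (ms) of the action potential evoked by one stimulus.

    ``stim_index`` selects among ``trace.stim_onsets`` (default: the last
    stimulus, i.e. the S2 beat when present).  The amplitude reference is
    peak V minus the sample immediately before stimulus onset, the start
    time is the instant of maximum dV/dt, and the 90%-repolarization
    crossing is linearly interpolated.
    """
    if not trace.stim_onsets:
        raise MeasurementError("trace carries no stimulus onset")
    onsets = sorted(trace.stim_onsets)
    onset = onsets[stim_index]
    later = [o for o in onsets if o > onset]
    t_end = later[0] if later else trace.t[-1]
    i_on = int(np.searchsorted(trace.t, onset - 1e-9))
    i_end = int(np.searchsorted(trace.t, t_end - 1e-9))
    seg = trace.v[i_on:i_end]
    if seg.size < 10:
        raise MeasurementError("stimulus segment too short")
    v_pre = trace.v[max(i_on - 1, 0)]
    peak = float(seg.max())
    if peak <= AP_PEAK_THRESHOLD:
        raise MeasurementError(
            f"no action potential detected (peak {peak:.1f} mV <= 0 mV)"
        )
    dv = np.diff(seg)
    i_up = int(dv.argmax())
    v90 = peak - 0.9 * (peak - v_pre)
    after = seg[i_up:]
    i_peak_rel = int(after.argmax())
    below = np.nonzero(after[i_peak_rel:] < v90)[0]
    if below.size == 0:
        raise MeasurementError("trace does not repolarize to 90% within segment")
    i_cross = i_up + i_peak_rel + int(below[0])
    frac = (v90 - seg[i_cross - 1]) / (seg[i_cross] - seg[i_cross - 1])
    t90 = (i_cross - 1 + frac) * trace.dt
    return float(t90 - i_up * trace.dt)


def _repol_time(trace: ApTrace, level: float, stim_index: int = 0) -> float:
    """Absolute time at which V crosses the given repolarization level."""
    onset = sorted(trace.stim_onsets)[stim_index]
    i_on = int(np.searchsorted(trace.t, onset - 1e-9))
    seg = trace.v[i_on:]
    v_pre = trace.v[max(i_on - 1, 0)]
    peak = float(seg.max())
    i_peak = int(seg.argmax())
    v_level = peak - level * (peak - v_pre)
    below = np.nonzero(seg[i_peak:] < v_level)[0]
    if below.size == 0:
        raise MeasurementError("trace does not repolarize within segment")
    i_cross = i_peak + int(below[0])
    return float(trace.t[i_on + i_cross])


class _SnapshotBank:
    """Conditioned-state snapshots on a 0.5 ms grid after the last S1 onset.

    Lets S2 trials restart from any candidate coupling interval without
    re-running the conditioning beats.
    """

    GRID = 0.5  # ms

    def __init__(self, p: CellParams, proto: StimulusProtocol, dt: float,
                 horizon: float):
        self.p = p
        self.dt = dt
        self.proto = proto
        state = resting_state(p, dt=dt).values.copy()
        P = p.to_array()
        last_onset = max(proto.n_beats - 1, 0) * proto.bcl
        n_steps = int(round((last_onset + horizon) / dt))
        stim_steps = np.array(
            [int(round(i * proto.bcl / dt)) for i in range(proto.n_beats)],
            np.int64,
        )
        grid_steps = int(round(self.GRID / dt))
        first = int(round(last_onset / dt))
        self.snap_steps = np.arange(first, n_steps, grid_steps, dtype=np.int64)
        stim_dur_steps = max(1, int(round(proto.s1_duration / dt)))
        v_rec, snaps = _run_cell(
            state, P, dt, n_steps, stim_steps, stim_dur_steps,
            proto.s1_amplitude, snap_steps=self.snap_steps,
        )
        self.snaps = snaps
        i0 = first
        self.last_beat = ApTrace(
            np.arange(v_rec.size - i0) * dt, v_rec[i0:], (0.0,), dt
        )

    def state_at(self, coupling: float) -> np.ndarray:
        idx = int(round(coupling / self.GRID))
        if not 0 <= idx < len(self.snaps):
            raise ProtocolError(
                f"coupling {coupling} ms outside the snapshot horizon"
            )
        return self.snaps[idx].copy()

    def s2_response_is_ap(self, coupling: float, window: float = 400.0) -> bool:
        return _is_regenerative_ap(
            self.s2_trace(coupling, window).v, self.dt, self.proto.s1_duration
        )

    def s2_trace(self, coupling: float, window: float = 600.0) -> ApTrace:
        state = self.state_at(coupling)
        P = self.p.to_array()
        n_steps = int(round(window / self.dt))
        stim_dur_steps = max(1, int(round(self.proto.s1_duration / self.dt)))
        v_rec, _ = _run_cell(
            state, P, self.dt, n_steps, np.array([0], np.int64),
            stim_dur_steps, self.proto.s1_amplitude,
        )
        return ApTrace(np.arange(v_rec.size) * self.dt, v_rec, (0.0,), self.dt)


def _is_regenerative_ap(v: np.ndarray, dt: float, stim_dur: float) -> bool:
    """An S2 response counts as an AP iff it overshoots 0 mV through a
    regenerative upstroke developing after the stimulus pulse.

    The explicit upstroke requirement (max dV/dt after the pulse above 20
    mV/ms) rejects two artifacts that satisfy a bare peak-above-zero rule:
    the still-positive plateau of the preceding beat, and the passive
    charging bump of a stimulus delivered into refractory tissue.
    """
    k0 = int(round(stim_dur / dt)) + 1
    tail = v[k0:]
    if tail.size < 3:
        return False
    dvdt = np.diff(tail).max() / dt
    return dvdt > AP_UPSTROKE_DVDT and float(tail.max()) > AP_PEAK_THRESHOLD


_BANK_CACHE: dict[tuple, _SnapshotBank] = {}


def _bank(p: CellParams, proto: StimulusProtocol, dt: float,
          horizon: float) -> _SnapshotBank:
    key = (p.to_array().tobytes(), proto, dt, horizon)
    if key not in _BANK_CACHE:
        if len(_BANK_CACHE) > 24:
            _BANK_CACHE.clear()
        _BANK_CACHE[key] = _SnapshotBank(p, proto, dt, horizon)
    return _BANK_CACHE[key]


def measure_erp(
    p: CellParams,
    proto: StimulusProtocol = StimulusProtocol(),
    dt: float = DT_DEFAULT,
    scan_start: float = 50.0,
    coarse_step: float = 5.0,
    resolution: float = 0.5,
) -> float:
    """Effective refractory period (ms) after the protocol's conditioning.

    Scans S1-S2 coupling intervals coarsely (5 ms) from ``scan_start`` until
    the S2 response qualifies as an AP (peak V > 0 mV), then bisects the
    bracket down to 0.5 ms and returns the earliest succeeding interval.
    """
    bank = _bank(p, proto, dt, horizon=proto.bcl + 100.0)
    c = scan_start
    prev_fail = None
    success = None
    while c <= proto.bcl:
        if bank.s2_response_is_ap(c):
            success = c
            break
        prev_fail = c
        c += coarse_step
    if success is None:
        raise ProtocolError("S2 never elicited an AP within one BCL")
    if prev_fail is None:
        raise ProtocolError(
            "S2 elicited an AP at every tested interval; lower scan_start"
        )
    lo, hi = prev_fail, success
    while hi - lo > resolution + 1e-9:
        mid = round((lo + hi) / 2.0 / resolution) * resolution
        if mid in (lo, hi):
            break
        if bank.s2_response_is_ap(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def restitution(
    p: CellParams,
    kind: str,
    abscissa: np.ndarray,
    dt: float = DT_DEFAULT,
    apd_proto: StimulusProtocol = StimulusProtocol(n_beats=10),
    erp_beats: int = 50,
) -> RestitutionCurve:
    """Restitution curve with its maximal finite-difference slope.

    ``kind`` is ``"APD-R"`` (abscissa = S2 coupling intervals; the curve is
    reported against the resulting diastolic intervals DI = coupling -
    APD90 of the conditioning beat) or ``"ERP-R"`` (abscissa = BCLs, with
    ``erp_beats`` conditioning beats at each BCL).
    """
    abscissa = np.asarray(abscissa, dtype=float)
    xs: list[float] = []
    ys: list[float] = []
    excluded: list[float] = []
    if kind == "APD-R":
        bank = _bank(p, apd_proto, dt, horizon=apd_proto.bcl + 100.0)
        apd_s1 = measure_apd90(bank.last_beat)
        for c in abscissa:
            try:
                tr = bank.s2_trace(float(c))
                if not _is_regenerative_ap(tr.v, dt, apd_proto.s1_duration):
                    raise MeasurementError("no regenerative S2 response")
                apd = measure_apd90(tr)
            except MeasurementError:
                excluded.append(float(c))
                log.warning("APD-R point at coupling %.1f ms failed AP detection", c)
                continue
            xs.append(float(c) - apd_s1)
            ys.append(apd)
    elif kind == "ERP-R":
        for bcl in abscissa:
            proto = StimulusProtocol(bcl=float(bcl), n_beats=erp_beats)
            try:
                erp = measure_erp(p, proto, dt=dt)
            except (ProtocolError, MeasurementError):
                excluded.append(float(bcl))
                log.warning("ERP-R point at BCL %.0f ms failed", bcl)
                continue
            xs.append(float(bcl))
            ys.append(erp)
    else:
        raise DomainError(f"unknown restitution kind {kind!r}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    return RestitutionCurve(kind, x, y, max_slope(x, y), tuple(excluded))


def max_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Maximal forward finite-difference slope of y(x) (no smoothing)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        return float("nan")
    return float((np.diff(y) / np.diff(x)).max())


def delta_v(a: ApTrace, b: ApTrace) -> tuple[np.ndarray, float]:
    """Pointwise membrane-potential difference a - b and its maximal
    magnitude during repolarization.

    The repolarization window runs from the later of the two peak times to
    the later of the two 95%-repolarization times.  Traces must share the
    sampling grid and stimulus alignment.
    """
    if abs(a.dt - b.dt) > 1e-12 or a.v.size != b.v.size:
        raise AlignmentError("traces do not share a sampling grid")
    if tuple(a.stim_onsets) != tuple(b.stim_onsets):
        raise AlignmentError("traces have different stimulus alignment")
    series = a.v - b.v
    t_peak = max(a.t[int(a.v.argmax())], b.t[int(b.v.argmax())])
    t95 = max(_repol_time(a, 0.95), _repol_time(b, 0.95))
    mask = (a.t >= t_peak) & (a.t <= t95)
    if not mask.any():
        raise MeasurementError("empty repolarization window")
    return series, float(np.abs(series[mask]).max())
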