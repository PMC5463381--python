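"""Monodomain 1D transmural fiber.

A 15 mm strand of 100 nodes (dx = 0.15 mm) spans the ventricular wall with
ENDO : MIDDLE : EPI cells in proportions 25% : 35% : 40%.  Voltage obeys

    dV/dt = -(I_ion + I_stim)/C_m + d/dx ( D dV/dx ),

discretized with per-face coupling coefficients (explicit forward Euler in
time, second-order central differences in space, no-flux ends).  The
coupling coefficient of the single MIDDLE-EPI junction face is reduced
fivefold, mimicking the sharp gap-junctional resistance transition of the
ventricular wall.  The default diffusion coefficient D = 8e-4 cm^2/ms
yields a conduction velocity near 52 cm/s.

The far-field (pseudo-)ECG of the strand is the line integral

    phi_e = (alpha^2 / 4) * Int (-dV/dx) d/dx(1/r) dx,

with alpha the strand radius and r the distance to an electrode placed
2.0 cm from the ENDO end (outside the strand, on the ENDO side), giving a
negative QRS and a positive T wave.  QT is measured from stimulus onset to
the last downward crossing of 0.01 mV after the T-wave peak.  alpha only
scales phi_e, but through the absolute T-end threshold it affects QT; the
default 2.4 mm places the 0.01 mV level at roughly 5% of the T-peak, which
makes the absolute criterion agree with the scale-free fallback
(``relative_threshold=0.05``) used to bound the sensitivity.

Temporal vulnerability: a premature stimulus (an S1-strength pulse on a
2.25 mm segment; see S2_SEGMENT_NODES) delivered into the wake of a
conditioning wave is classified as bidirectional block, unidirectional
block or bidirectional conduction from sentinel re-activation at the two
fiber ends; the vulnerable window is the contiguous range of timings that
produce unidirectional block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .cell_protocols import StimulusProtocol
from .drug_block import BlockTable, apply_drug
from .errors import (
    ConfigError,
    DomainError,
    InstabilityError,
    MeasurementError,
    ProtocolError,
)
from .ionic_cell import CellParams, CellType, Ik1Variant, resting_state

__all__ = [
    "FiberConfig",
    "FiberModel",
    "SpaceTimeField",
    "EcgTrace",
    "VulnerabilityResult",
    "build_fiber",
    "simulate_fiber",
    "measure_cv",
    "pseudo_ecg",
    "apd_profile",
    "vulnerable_window",
]

UPSTROKE_THRESHOLD = -20.0  # mV, activation detection
T_END_THRESHOLD = 0.01      # mV, absolute T-end criterion
QRS_END_MS = 80.0           # ms after Q onset; start of the T-wave search


@dataclass(frozen=True)
class FiberConfig:
    """Geometry/numerics of the transmural strand."""

    length_mm: float = 15.0
    nx: int = 100
    dx_mm: float = 0.15
    diffusion_cm2_ms: float = 0.0008
    proportions: tuple[float, float, float] = (25.0, 35.0, 40.0)  # ENDO/MID/EPI %
    junction_factor: float = 0.2   # MIDDLE-EPI face coupling multiplier (1/5)
    electrode_cm: float = 2.0      # distance from the ENDO end, ENDO side
    alpha_mm: float = 2.4          # strand radius in the ECG integral
    dt_ms: float = 0.02

    def __post_init__(self):
        if abs(self.nx * self.dx_mm - self.length_mm) > 1e-9:
            raise ConfigError("nx * dx must equal the fiber length")
        if abs(sum(self.proportions) - 100.0) > 1e-9:
            raise ConfigError("region proportions must sum to 100%")
        for frac in self.proportions:
            n = self.nx * frac / 100.0
            if abs(n - round(n)) > 1e-9:
                raise ConfigError(
                    "region proportions must resolve to whole node counts"
                )
        dx_cm = self.dx_mm / 10.0
        if self.diffusion_cm2_ms * self.dt_ms / dx_cm**2 >= 0.5:
            raise ConfigError("explicit-scheme stability violated: D*dt/dx^2 >= 0.5")

    @property
    def region_nodes(self) -> tuple[int, int, int]:
        return tuple(int(round(self.nx * f / 100.0)) for f in self.proportions)

    @property
    def dx_cm(self) -> float:
        return self.dx_mm / 10.0


@dataclass
class FiberModel:
    """Assembled strand: per-node parameters and face couplings."""

    config: FiberConfig
    node_types: list[CellType]
    node_params: list[CellParams]
    P: np.ndarray = field(repr=False)     # (nx, NPARAM)
    w: np.ndarray = field(repr=False)     # (nx-1,) face couplings, ms^-1

    @property
    def junction_face(self) -> int:
        n_endo, n_mid, _ = self.config.region_nodes
        return n_endo + n_mid - 1


@dataclass
class SpaceTimeField:
    """Recorded V(node, time) with the stimulus log."""

    t: np.ndarray                         # ms
    v: np.ndarray = field(repr=False)     # (nt, nx) mV
    node_types: list[CellType]
    config: FiberConfig
    s1_onsets: tuple[float, ...]
    s2_onset: float | None = None

    @property
    def dt_sample(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class EcgTrace:
    """Pseudo-ECG with its scalar metrics."""

    t: np.ndarray
    phie: np.ndarray = field(repr=False)   # mV
    q_onset_ms: float = 0.0
    t_peak_ms: float = float("nan")
    t_end_ms: float = float("nan")
    qt_ms: float = float("nan")
    t_amp_mV: float = float("nan")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.t, "phie_mV": self.phie})


@dataclass
class VulnerabilityResult:
    """Premature-stimulus outcome map and the vulnerable window."""

    site: str                               # "ENDO" | "EPI"
    outcomes: dict[float, str]              # timing -> classification
    window_start: float | None
    window_end: float | None
    multi_interval: bool = False

    @property
    def width(self) -> float:
        if self.window_start is None:
            return 0.0
        return self.window_end - self.window_start


def default_region_params(
    variant: Ik1Variant | str = Ik1Variant.WT,
    drug_table: BlockTable | None = None,
) -> dict[CellType, CellParams]:
    """Per-region parameter sets for a genotype, with optional drug block."""
    out = {}
    for ct in CellType:
        p = CellParams.default(ct, variant)
        out[ct] = apply_drug(p, drug_table)
    return out


def build_fiber(
    cfg: FiberConfig = FiberConfig(),
    params: dict[CellType, CellParams] | None = None,
    drug_table: BlockTable | None = None,
    variant: Ik1Variant | str = Ik1Variant.WT,
) -> FiberModel:
    """Assemble the heterogeneous strand.

    ``params`` maps each region's cell type to its parameter set (defaults
    to the published sets for ``variant``); ``drug_table`` is applied on
    top.  The single MIDDLE-EPI junction face coupling is multiplied by
    ``cfg.junction_factor``.
    """
    if params is None:
        params = default_region_params(variant, drug_table)
    elif drug_table is not None:
        params = {ct: apply_drug(p, drug_table) for ct, p in params.items()}
    n_endo, n_mid, n_epi = cfg.region_nodes
    node_types = (
        [CellType.ENDO] * n_endo + [CellType.MIDDLE] * n_mid + [CellType.EPI] * n_epi
    )
    node_params = [params[ct] for ct in node_types]
    P = np.stack([p.to_array() for p in node_params])
    w = np.full(cfg.nx - 1, cfg.diffusion_cm2_ms / cfg.dx_cm**2)
    if n_epi > 0 and n_mid > 0:
        w[n_endo + n_mid - 1] *= cfg.junction_factor
    return FiberModel(cfg, node_types, node_params, P, w)


_FIBER_REST_CACHE: dict[bytes, np.ndarray] = {}


def fiber_resting_states(f: FiberModel, settle_ms: float = 200.0) -> np.ndarray:
    """(nx, NSTATE) resting states: per-type cell rest plus a coupled settle."""
    key = f.P.tobytes() + f.w.tobytes() + np.float64([settle_ms]).tobytes()
    if key not in _FIBER_REST_CACHE:
        S = np.stack(
            [resting_state(p, dt=f.config.dt_ms).values for p in f.node_params]
        )
        if settle_ms > 0:
            _integrate(f, S, settle_ms, np.empty(0, np.int64), rec_stride=10**9)
        _FIBER_REST_CACHE[key] = S
    return _FIBER_REST_CACHE[key].copy()


def _integrate(
    f: FiberModel,
    S: np.ndarray,
    duration_ms: float,
    s1_steps: np.ndarray,
    s1_nodes: tuple[int, int] = (0, 3),
    s2_step: int = -1,
    s2_nodes: tuple[int, int] = (0, 0),
    stim_amp: float = -52.0,
    stim_dur_ms: float = 1.0,
    rec_stride: int = 5,
    snap_steps: np.ndarray | None = None,
):
    cfg = f.config
    n_steps = int(round(duration_ms / cfg.dt_ms))
    n_rec = n_steps // rec_stride + 1 if rec_stride <= n_steps else 1
    v_rec = np.empty((n_rec, cfg.nx))
    if snap_steps is None:
        snap_steps = np.empty(0, np.int64)
    snaps = np.empty((len(snap_steps), cfg.nx, _kernel.NSTATE))
    status = _kernel.integrate_fiber(
        S, f.P, _kernel.rate_table(cfg.dt_ms), f.w, cfg.dt_ms, n_steps,
        s1_nodes[0], s1_nodes[1], s1_steps,
        s2_nodes[0], s2_nodes[1], s2_step,
        max(1, int(round(stim_dur_ms / cfg.dt_ms))), stim_amp,
        rec_stride, v_rec, snap_steps, snaps,
    )
    if status >= 0:
        raise InstabilityError(
            f"fiber integration diverged at t = {status * cfg.dt_ms:.2f} ms",
            t_ms=status * cfg.dt_ms,
        )
    t = np.arange(n_rec) * cfg.dt_ms * rec_stride
    return t, v_rec, snaps


def simulate_fiber(
    f: FiberModel,
    proto: StimulusProtocol = StimulusProtocol(n_beats=1),
    duration_ms: float | None = None,
    rec_stride: int = 5,
    keep_last_beat_only: bool = True,
) -> SpaceTimeField:
    """Pace the strand from its resting state with S1 applied to the first
    three ENDO nodes; returns the recorded field (last beat by default)."""
    cfg = f.config
    if duration_ms is None:
        duration_ms = proto.n_beats * proto.bcl
    S = fiber_resting_states(f)
    s1_steps = np.array(
        [int(round(i * proto.bcl / cfg.dt_ms)) for i in range(proto.n_beats)],
        np.int64,
    )
    t, v, _ = _integrate(
        f, S, duration_ms, s1_steps, stim_amp=proto.s1_amplitude,
        stim_dur_ms=proto.s1_duration, rec_stride=rec_stride,
    )
    onsets = tuple(i * proto.bcl for i in range(proto.n_beats))
    if keep_last_beat_only and proto.n_beats > 1:
        t0 = onsets[-1]
        i0 = int(np.searchsorted(t, t0 - 1e-9))
        t, v = t[i0:] - t[i0], v[i0:]
        onsets = (0.0,)
    return SpaceTimeField(t, v, list(f.node_types), cfg, onsets)


def activation_times(
    field: SpaceTimeField, after_ms: float = 0.0,
    threshold: float = UPSTROKE_THRESHOLD,
) -> np.ndarray:
    """Per-node first upward threshold crossing after ``after_ms`` (ms).

    Nodes that never activate get NaN.
    """
    t, v = field.t, field.v
    i0 = int(np.searchsorted(t, after_ms))
    out = np.full(v.shape[1], np.nan)
    for i in range(v.shape[1]):
        col = v[i0:, i]
        above = np.nonzero((col[1:] >= threshold) & (col[:-1] < threshold))[0]
        if above.size:
            k = int(above[0])
            frac = (threshold - col[k]) / (col[k + 1] - col[k])
            out[i] = t[i0 + k] + frac * field.dt_sample
    return out


def measure_cv(field: SpaceTimeField, lo_node: int = 10, hi_node: int = 55) -> float:
    """Conduction velocity (cm/s) from activation-time regression.

    Regresses activation time on distance over the homogeneous
    ENDO-MIDDLE stretch (default nodes 10..54, clear of the stimulus site
    and of the reduced-coupling junction).  Returns NaN (propagation
    failure) if any node in the stretch never activates.
    """
    act = activation_times(field)
    seg = act[lo_node:hi_node]
    if np.any(np.isnan(seg)):
        return float("nan")
    x_cm = np.arange(lo_node, hi_node) * field.config.dx_cm
    slope = np.polyfit(x_cm, seg, 1)[0]     # ms/cm
    if slope <= 0:
        return float("nan")
    return float(1000.0 / slope)            # cm/s


def pseudo_ecg(
    field: SpaceTimeField,
    cfg: FiberConfig | None = None,
    relative_threshold: float | None = None,
) -> EcgTrace:
    """Far-field potential of the strand and its QT / T-wave metrics.

    ``relative_threshold`` switches the T-end criterion from the absolute
    0.01 mV level to the given fraction of the T-peak amplitude (the
    scale-free fallback that removes the dependence on the strand radius).
    """
    cfg = cfg or field.config
    x = np.arange(cfg.nx) * cfg.dx_cm                  # cm
    xe = -cfg.electrode_cm                             # ENDO side, outside
    r = np.abs(x - xe)
    if np.any(r < cfg.dx_cm):
        raise ConfigError("electrode must lie outside the strand")
    dinv = np.gradient(1.0 / r, x)                     # d/dx (1/r)
    alpha_cm = cfg.alpha_mm / 10.0
    dvdx = np.gradient(field.v, x, axis=1)
    phie = (alpha_cm**2 / 4.0) * np.sum((-dvdx) * dinv, axis=1) * cfg.dx_cm
    q_onset = field.s1_onsets[-1] if field.s1_onsets else 0.0
    trace = EcgTrace(field.t, phie, q_onset_ms=q_onset)
    i_qrs_end = int(np.searchsorted(field.t, q_onset + QRS_END_MS))
    if i_qrs_end >= field.t.size - 2:
        raise MeasurementError("field too short for T-wave analysis")
    tail = phie[i_qrs_end:]
    i_peak = i_qrs_end + int(tail.argmax())
    t_amp = float(phie[i_peak])
    thresh = (
        T_END_THRESHOLD if relative_threshold is None
        else relative_threshold * t_amp
    )
    if t_amp <= thresh:
        raise MeasurementError("pseudo-ECG never exceeds the T-end threshold")
    after = phie[i_peak:]
    below = np.nonzero(after < thresh)[0]
    if below.size == 0:
        raise MeasurementError("T wave does not return below threshold")
    k = i_peak + int(below[0])
    frac = (phie[k - 1] - thresh) / (phie[k - 1] - phie[k])
    t_end = float(field.t[k - 1] + frac * field.dt_sample)
    trace.t_peak_ms = float(field.t[i_peak])
    trace.t_end_ms = t_end
    trace.qt_ms = t_end - q_onset
    trace.t_amp_mV = t_amp
    return trace


def apd_profile(field: SpaceTimeField):
    """Per-node APD90, its spatial gradient (ms/mm) and the max |gradient|.

    Returns ``(apd, grad, max_abs_grad, argmax_node)``; nodes that fail AP
    detection are NaN (flagged, excluded from the maximum).
    """
    t, v = field.t, field.v
    onset = field.s1_onsets[-1] if field.s1_onsets else 0.0
    i_on = int(np.searchsorted(t, onset - 1e-9))
    apd = np.full(v.shape[1], np.nan)
    for i in range(v.shape[1]):
        col = v[i_on:, i]
        v_pre = v[max(i_on - 1, 0), i]
        peak = float(col.max())
        if peak <= 0.0:
            continue
        dv = np.diff(col)
        i_up = int(dv.argmax())
        v90 = peak - 0.9 * (peak - v_pre)
        i_pk = i_up + int(col[i_up:].argmax())
        below = np.nonzero(col[i_pk:] < v90)[0]
        if below.size == 0:
            continue
        k = i_pk + int(below[0])
        frac = (v90 - col[k - 1]) / (col[k] - col[k - 1])
        apd[i] = (k - 1 + frac - i_up) * field.dt_sample
    x_mm = np.arange(v.shape[1]) * field.config.dx_mm
    grad = np.gradient(apd, x_mm)
    finite = np.isfinite(grad)
    if not finite.any():
        raise MeasurementError("no node produced a measurable APD")
    idx = int(np.nanargmax(np.abs(grad)))
    return apd, grad, float(abs(grad[idx])), idx


#: premature-stimulus segment width (nodes).  With the S1-strength pulse
#: (-52 pA/pF, 1 ms), narrower segments cannot overcome the electrotonic
#: load of partially recovered tissue until long after repolarization, so
#: no unidirectional window exists; 15 nodes (2.25 mm) restores capture
#: shortly after local recovery (see docs/methods.md).
S2_SEGMENT_NODES = 15


def _site_nodes(f: FiberModel, site: str,
                width: int = S2_SEGMENT_NODES) -> tuple[int, int]:
    n_endo, n_mid, n_epi = f.config.region_nodes
    if site == "ENDO":
        c = n_endo // 2
    elif site == "EPI":
        c = n_endo + n_mid + n_epi // 2
    else:
        raise DomainError("site must be 'ENDO' or 'EPI'")
    lo = max(c - width // 2, 0)
    return (lo, min(lo + width, f.config.nx))


_VW_SNAP_CACHE: dict[tuple, tuple] = {}


def _vw_snapshots(f: FiberModel, timings: np.ndarray, stim_amp, stim_dur):
    """Conditioning S1 wave once; full fiber states at every S2 timing."""
    key = (f.P.tobytes(), f.w.tobytes(), timings.tobytes())
    if key not in _VW_SNAP_CACHE:
        cfg = f.config
        S = fiber_resting_states(f)
        snap_steps = np.array(
            [int(round(tm / cfg.dt_ms)) for tm in timings], np.int64
        )
        _, _, snaps = _integrate(
            f, S, float(timings.max()) + cfg.dt_ms, np.array([0], np.int64),
            stim_amp=stim_amp, stim_dur_ms=stim_dur,
            rec_stride=10**9, snap_steps=snap_steps,
        )
        if len(_VW_SNAP_CACHE) > 8:
            _VW_SNAP_CACHE.clear()
        _VW_SNAP_CACHE[key] = (snap_steps, snaps)
    return _VW_SNAP_CACHE[key]


def classify_premature(
    f: FiberModel,
    site: str,
    s2_time: float,
    proto: StimulusProtocol = StimulusProtocol(n_beats=1),
    follow_ms: float = 250.0,
    _snapshot_grid: np.ndarray | None = None,
) -> str:
    """Outcome of one premature stimulus at ``s2_time`` ms after the
    conditioning S1: 'bidirectional block', 'unidirectional block' or
    'bidirectional conduction' (sentinel re-activation of the fiber ends).
    """
    cfg = f.config
    grid = (
        _snapshot_grid if _snapshot_grid is not None
        else np.array([s2_time], dtype=float)
    )
    snap_steps, snaps = _vw_snapshots(f, grid, proto.s1_amplitude, proto.s1_duration)
    idx = int(np.argmin(np.abs(grid - s2_time)))
    if abs(grid[idx] - s2_time) > 1e-9:
        raise ProtocolError("s2_time not on the snapshot grid")
    S = snaps[idx].copy()
    lo, hi = _site_nodes(f, site)
    t, v, _ = _integrate(
        f, S, follow_ms, np.empty(0, np.int64),
        s2_step=0, s2_nodes=(lo, hi),
        stim_amp=proto.s1_amplitude, stim_dur_ms=proto.s1_duration,
        rec_stride=5,
    )
    # a fiber end counts as re-activated when it crosses the upstroke
    # threshold upward after having been below it
    reactivated = 0
    for end in (0, cfg.nx - 1):
        col = v[:, end]
        below = col < UPSTROKE_THRESHOLD
        crossed = np.nonzero(below[:-1] & (col[1:] >= UPSTROKE_THRESHOLD))[0]
        if crossed.size:
            reactivated += 1
    return {
        0: "bidirectional block",
        1: "unidirectional block",
        2: "bidirectional conduction",
    }[reactivated]


def vulnerable_window(
    f: FiberModel,
    site: str,
    scan_range: tuple[float, float],
    resolution: float = 0.5,
    method: str = "scan",
    proto: StimulusProtocol = StimulusProtocol(n_beats=1),
    follow_ms: float = 250.0,
) -> VulnerabilityResult:
    """Vulnerable window of premature-stimulus timings at one site.

    ``method='scan'`` classifies every timing on the resolution grid (the
    reference procedure); ``method='bisect'`` classifies the range ends
    plus a coarse 2 ms sweep to find the unidirectional interval, then
    bisects its two edges to ``resolution`` (equivalent when the
    unidirectional set is contiguous, which the scan method verifies).
    """
    t0, t1 = scan_range
    if t1 <= t0:
        raise DomainError("empty scan range")
    grid = np.round(np.arange(t0, t1 + resolution / 2, resolution), 6)
    outcomes: dict[float, str] = {}

    def cls(tm: float) -> str:
        tm = float(tm)
        if tm not in outcomes:
            outcomes[tm] = classify_premature(
                f, site, tm, proto, follow_ms, _snapshot_grid=grid
            )
        return outcomes[tm]

    if method == "scan":
        for tm in grid:
            cls(tm)
        uni = [tm for tm in grid if outcomes[float(tm)] == "unidirectional block"]
        if not uni:
            return VulnerabilityResult(site, outcomes, None, None)
        runs = np.split(np.array(uni), np.nonzero(np.diff(uni) > resolution * 1.5)[0] + 1)
        multi = len(runs) > 1
        longest = max(runs, key=len)
        return VulnerabilityResult(
            site, outcomes, float(longest[0]), float(longest[-1]), multi
        )
    if method != "bisect":
        raise DomainError("method must be 'scan' or 'bisect'")

    coarse = grid[:: max(1, int(round(2.0 / resolution)))]
    hit = None
    for tm in coarse:
        if cls(tm) == "unidirectional block":
            hit = float(tm)
            break
    if hit is None:
        for tm in grid:     # fall back to the full grid before giving up
            if cls(tm) == "unidirectional block":
                hit = float(tm)
                break
    if hit is None:
        return VulnerabilityResult(site, outcomes, None, None)

    def snap(x):
        return float(np.round(x / resolution) * resolution)

    def first_uni(lo, hi):
        # cls(lo) != uni, cls(hi) == uni; smallest unidirectional timing
        while hi - lo > resolution + 1e-9:
            mid = snap((lo + hi) / 2)
            if mid <= lo or mid >= hi:
                break
            if cls(mid) == "unidirectional block":
                hi = mid
            else:
                lo = mid
        return hi

    def last_uni(lo, hi):
        # cls(lo) == uni, cls(hi) != uni; largest unidirectional timing
        while hi - lo > resolution + 1e-9:
            mid = snap((lo + hi) / 2)
            if mid <= lo or mid >= hi:
                break
            if cls(mid) == "unidirectional block":
                lo = mid
            else:
                hi = mid
        return lo

    lo = float(grid[0])
    start = lo if cls(lo) == "unidirectional block" else first_uni(lo, hit)
    hi = float(grid[-1])
    end = hi if cls(hi) == "unidirectional block" else last_uni(hit, hi)
    return VulnerabilityResult(site, outcomes, start, end, False)
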