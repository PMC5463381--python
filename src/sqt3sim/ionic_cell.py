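"""Single-cell human ventricular action-potential model.

The baseline formulation is the 2006 ten Tusscher-Panfilov human ventricular
model with endocardial (ENDO), mid-myocardial (MIDDLE) and epicardial (EPI)
parameter sets, extended with the late sodium current of the O'Hara-Rudy
model (non-phosphorylated gating, flux added to the Na+ balance) and a
variant-aware inward-rectifier current

    I_K1 = G_K1 * sqrt(K_o / 5.4) * s * x_K1inf(V - E_K; dV, k) * (V - E_K)

where the per-variant multiplicative scale ``s``, rightward shift ``dV`` and
steepness ``k`` of the rectification cutoff encode the gain-of-function
Kir2.1 D172N kinetics (heterozygous WT-D172N and homozygous D172N) without
moving the reversal potential.  Calibrated variant constants live in
``data/ik1_variants.yaml`` (see :mod:`sqt3sim.clamp_fit`).

Integration is forward Euler for voltage and concentrations (default time
step 0.02 ms) and Rush-Larsen exponential updates for the Hodgkin-Huxley
gates; gates stay in [0, 1] by construction and are never clipped.
"""

from __future__ import annotations

import csv
import enum
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import _kernel
from ._kernel import NCURRENT, NPARAM, NSTATE
from .errors import DomainError, InstabilityError, IntegrityError

__all__ = [
    "CellType",
    "Ik1Variant",
    "Ik1Params",
    "CellParams",
    "CellState",
    "CurrentBreakdown",
    "ik1_current",
    "compute_currents",
    "step_cell",
    "initial_state",
    "resting_state",
]

DT_DEFAULT = 0.02  # ms

STATE_NAMES = (
    "V", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
    "fcass", "rr", "ml", "hl", "cai", "casr", "cass", "nai", "ki",
)
STATE_UNITS = (
    "mV", "1", "1", "1", "1", "1", "1", "1", "1", "1", "1", "1",
    "1", "1", "1", "1", "mM", "mM", "mM", "mM", "mM",
)
GATE_INDICES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15)

CURRENT_NAMES = (
    "I_Na", "I_NaL", "I_CaL", "I_to", "I_Kr", "I_Ks", "I_K1",
    "I_NaCa", "I_NaK", "I_pCa", "I_pK", "I_bNa", "I_bCa", "I_ion",
)


class CellType(enum.Enum):
    ENDO = "ENDO"
    MIDDLE = "MIDDLE"
    EPI = "EPI"


class Ik1Variant(enum.Enum):
    WT = "WT"
    WT_D172N = "WT-D172N"
    D172N = "D172N"


def _load_variant_registry():
    ref = importlib.resources.files("sqt3sim") / "data" / "ik1_variants.yaml"
    with ref.open("r") as fh:
        raw = yaml.safe_load(fh)
    return {
        Ik1Variant(k): (float(v["scale"]), float(v["shift_mV"]), float(v["slope"]))
        for k, v in raw["variants"].items()
    }


_VARIANT_REGISTRY = None


def variant_scale_shift(variant: Ik1Variant) -> tuple[float, float, float]:
    """Calibrated (scale, shift_mV, slope) from the packaged variant registry."""
    global _VARIANT_REGISTRY
    if _VARIANT_REGISTRY is None:
        _VARIANT_REGISTRY = _load_variant_registry()
    return _VARIANT_REGISTRY[variant]


@dataclass(frozen=True)
class Ik1Params:
    """Inward-rectifier parameters.

    The rectification factor keeps the baseline functional form (see
    :func:`sqt3sim._kernel.xk1_inf`); a variant is expressed through a
    multiplicative ``scale``, a rightward shift (``shift_mV``) of the
    rectification-cutoff exponential and its steepness (``slope``), all of
    which leave the reversal potential untouched.
    """

    g_k1: float = 5.405      # nS/pF
    k_o: float = 5.4         # mM
    scale: float = 1.0
    shift_mV: float = 0.0
    slope: float = 0.1       # mV-1, rectification cutoff steepness

    def __post_init__(self):
        if self.g_k1 <= 0:
            raise DomainError("G_K1 must be positive")
        if self.k_o <= 0:
            raise DomainError("K_o must be positive")
        if self.scale <= 0:
            raise DomainError("I_K1 variant scale must be positive")
        if self.slope <= 0:
            raise DomainError("I_K1 rectification slope must be positive")

    def for_variant(self, variant: Ik1Variant) -> "Ik1Params":
        scale, shift, slope = variant_scale_shift(variant)
        return replace(self, scale=scale, shift_mV=shift, slope=slope)


# baseline maximal conductances (ENDO, MIDDLE, EPI differ in I_to and I_Ks)
_G_TO = {CellType.ENDO: 0.073, CellType.MIDDLE: 0.294, CellType.EPI: 0.294}
_G_KS = {CellType.ENDO: 0.392, CellType.MIDDLE: 0.098, CellType.EPI: 0.392}

#: Late sodium conductance (mS/uF).  The donor model's endocardial value is
#: 0.0075; it is used unchanged for all three cell types (see docs/methods).
G_NAL_DEFAULT = 0.0075


@dataclass(frozen=True)
class CellParams:
    """Maximal conductances/permeabilities of one ventricular cell.

    Units follow the baseline model: conductances in nS/pF, g_cal in
    cm3 uF-1 s-1, p_nak and k_naca in pA/pF, concentrations in mM,
    membrane capacitance cm in uF/cm2 (current densities in pA/pF make the
    voltage equation independent of its absolute value).
    """

    cell_type: CellType = CellType.EPI
    variant: Ik1Variant = Ik1Variant.WT
    g_na: float = 14.838
    g_cal: float = 3.98e-5
    g_kr: float = 0.153
    g_ks: float = 0.392
    g_to: float = 0.294
    ik1: Ik1Params = field(default_factory=Ik1Params)
    g_nal: float = G_NAL_DEFAULT
    p_nak: float = 2.724
    k_naca: float = 1000.0
    g_bna: float = 0.00029
    g_bca: float = 0.000592
    g_pk: float = 0.0146
    g_pca: float = 0.1238
    na_o: float = 140.0
    ca_o: float = 2.0
    cm: float = 1.0

    def __post_init__(self):
        for name in ("g_na", "g_cal", "g_kr", "g_ks", "g_to", "g_nal",
                     "p_nak", "k_naca", "g_bna", "g_bca", "g_pk", "g_pca"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    @classmethod
    def default(
        cls,
        cell_type: CellType | str = CellType.EPI,
        variant: Ik1Variant | str = Ik1Variant.WT,
    ) -> "CellParams":
        """Published conductance set for a cell type with a calibrated variant."""
        cell_type = CellType(cell_type) if not isinstance(cell_type, CellType) else cell_type
        variant = Ik1Variant(variant) if not isinstance(variant, Ik1Variant) else variant
        return cls(
            cell_type=cell_type,
            variant=variant,
            g_to=_G_TO[cell_type],
            g_ks=_G_KS[cell_type],
            ik1=Ik1Params().for_variant(variant),
        )

    def to_array(self) -> np.ndarray:
        p = np.empty(NPARAM)
        p[0] = self.g_na
        p[1] = self.g_cal
        p[2] = self.g_kr
        p[3] = self.g_ks
        p[4] = self.g_to
        p[5] = self.ik1.g_k1
        p[6] = self.g_nal
        p[7] = self.p_nak
        p[8] = self.k_naca
        p[9] = self.g_bna
        p[10] = self.g_bca
        p[11] = self.g_pk
        p[12] = self.g_pca
        p[13] = self.ik1.k_o
        p[14] = self.na_o
        p[15] = self.ca_o
        p[16] = self.ik1.scale
        p[17] = self.ik1.shift_mV
        p[18] = 1.0 if self.cell_type is CellType.ENDO else 0.0
        p[19] = self.ik1.slope
        return p

    def replace(self, **kw) -> "CellParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = {
            "cell_type": self.cell_type.value,
            "variant": self.variant.value,
        }
        for name in ("g_na", "g_cal", "g_kr", "g_ks", "g_to", "g_nal",
                     "p_nak", "k_naca", "g_bna", "g_bca", "g_pk", "g_pca",
                     "na_o", "ca_o", "cm"):
            d[name] = float(getattr(self, name))
        d["ik1"] = {
            "g_k1": self.ik1.g_k1, "k_o": self.ik1.k_o,
            "scale": self.ik1.scale, "shift_mV": self.ik1.shift_mV,
            "slope": self.ik1.slope,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellParams":
        d = dict(d)
        ik1 = Ik1Params(**d.pop("ik1"))
        return cls(cell_type=CellType(d.pop("cell_type")),
                   variant=Ik1Variant(d.pop("variant")), ik1=ik1, **d)


@dataclass
class CellState:
    """Full dynamical state of one cell at time t."""

    values: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (NSTATE,):
            raise IntegrityError(f"state vector must have length {NSTATE}")

    @property
    def v(self) -> float:
        return float(self.values[0])

    def __getattr__(self, name):
        try:
            idx = STATE_NAMES.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return float(self.values[idx])

    def copy(self) -> "CellState":
        return CellState(self.values.copy(), self.t)

    def validate(self):
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("state contains NaN or inf")
        gates = self.values[list(GATE_INDICES)]
        if np.any(gates < -1e-12) or np.any(gates > 1.0 + 1e-12):
            raise IntegrityError("gating variable outside [0, 1]")
        if np.any(self.values[16:] <= 0):
            raise IntegrityError("non-positive ionic concentration")

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "value", "unit"])
            for name, val, unit in zip(STATE_NAMES, self.values, STATE_UNITS):
                w.writerow([name, repr(float(val)), unit])
            w.writerow(["t", repr(self.t), "ms"])

    @classmethod
    def from_csv(cls, path) -> "CellState":
        vals = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                vals[row["name"]] = float(row["value"])
        values = np.array([vals[n] for n in STATE_NAMES])
        return cls(values, t=vals.get("t", 0.0))


@dataclass(frozen=True)
class CurrentBreakdown:
    """Per-current membrane densities (pA/pF)."""

    i_na: float
    i_nal: float
    i_cal: float
    i_to: float
    i_kr: float
    i_ks: float
    i_k1: float
    i_naca: float
    i_nak: float
    i_pca: float
    i_pk: float
    i_bna: float
    i_bca: float
    i_ion: float

    def as_dict(self) -> dict[str, float]:
        return {n: v for n, v in zip(CURRENT_NAMES, self.as_array())}

    def as_array(self) -> np.ndarray:
        return np.array([
            self.i_na, self.i_nal, self.i_cal, self.i_to, self.i_kr,
            self.i_ks, self.i_k1, self.i_naca, self.i_nak, self.i_pca,
            self.i_pk, self.i_bna, self.i_bca, self.i_ion,
        ])


def ik1_current(
    v: float,
    k_i: float,
    k_o: float,
    p: Ik1Params,
    variant: Ik1Variant | None = None,
) -> float:
    """Inward-rectifier current density (pA/pF) at voltage ``v``.

    When ``variant`` is given, the calibrated scale/shift of that variant
    override the ones carried by ``p``.
    """
    if k_o <= 0 or k_i <= 0:
        raise DomainError("potassium concentrations must be positive")
    if variant is not None:
        p = p.for_variant(variant)
    return float(
        _kernel.ik1_density(v, k_i, k_o, p.g_k1, p.scale, p.shift_mV, p.slope)
    )


def compute_currents(state: CellState, params: CellParams) -> CurrentBreakdown:
    """All membrane currents at ``state``; deterministic, no side effects."""
    state.validate()
    out = np.empty(NCURRENT)
    _kernel.compute_currents(state.values, params.to_array(), out)
    return CurrentBreakdown(*out)


def step_cell(
    state: CellState,
    params: CellParams,
    i_stim: float = 0.0,
    dt: float = DT_DEFAULT,
    rush_larsen: bool = True,
) -> CellState:
    """Advance one cell by one time step and return the new state."""
    if dt <= 0:
        raise DomainError("dt must be positive")
    new = state.copy()
    dv = _kernel.step_node(new.values, params.to_array(), i_stim, dt, rush_larsen)
    new.values[0] += dt * dv
    new.t = state.t + dt
    if abs(new.values[0]) > _kernel.V_DIVERGED:
        raise InstabilityError(
            f"membrane voltage diverged at t = {new.t:.3f} ms", t_ms=new.t
        )
    return new


def initial_state() -> CellState:
    """Published baseline initial conditions (quiescent, near rest)."""
    vals = np.zeros(NSTATE)
    vals[0] = -86.2    # V
    vals[2] = 0.75     # h
    vals[3] = 0.75     # j
    vals[5] = 1.0      # xr2
    vals[8] = 1.0      # s
    vals[10] = 1.0     # f
    vals[11] = 1.0     # f2
    vals[12] = 1.0     # fcass
    vals[13] = 1.0     # rr
    vals[15] = 0.45    # hl
    vals[16] = 0.00007
    vals[17] = 1.3
    vals[18] = 0.00007
    vals[19] = 7.67
    vals[20] = 138.3
    return CellState(vals)


def dump_canonical_params(path) -> None:
    """Write the canonical parameter file: one block per cell type and
    I_K1 variant, all constants in the units of the dataclasses."""
    blocks = {}
    for ct in CellType:
        for var in Ik1Variant:
            blocks[f"{ct.value}/{var.value}"] = CellParams.default(ct, var).to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(blocks, fh, sort_keys=True)


def load_canonical_params(path) -> dict[tuple[CellType, Ik1Variant], CellParams]:
    with open(path) as fh:
        blocks = yaml.safe_load(fh)
    out = {}
    for p in map(CellParams.from_dict, blocks.values()):
        out[p.cell_type, p.variant] = p
    return out


_REST_CACHE: dict[bytes, np.ndarray] = {}


def resting_state(params: CellParams, settle_ms: float = 10000.0,
                  dt: float = DT_DEFAULT) -> CellState:
    """Committed resting state: quiescent settling from the baseline ICs.

    Results are cached per parameter set within a process.
    """
    p = params.to_array()
    key = p.tobytes() + np.float64([settle_ms, dt]).tobytes()
    if key not in _REST_CACHE:
        s = initial_state().values.copy()
        n_steps = int(round(settle_ms / dt))
        v_rec = np.empty(2)
        no_stim = np.empty(0, dtype=np.int64)
        no_snap = np.empty(0, dtype=np.int64)
        snaps = np.empty((0, NSTATE))
        status = _kernel.integrate_cell(
            s, p, dt, n_steps, no_stim, 0, 0.0, n_steps, v_rec, no_snap,
            snaps, True,
        )
        if status >= 0:
            raise InstabilityError(
                f"divergence during quiescent settling at t = {status * dt:.2f} ms",
                t_ms=status * dt,
            )
        _REST_CACHE[key] = s
    return CellState(_REST_CACHE[key].copy(), t=0.0)
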