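"""Tonic pore-block drug model.

A drug at concentration [D] (uM) reduces the maximal conductance of a
channel according to the blocking fraction

    theta = 1 / (1 + (IC50 / [D])**nH),

so the conductance retains a fraction 1 - theta = 1 / (1 + ([D]/IC50)**nH)
of its drug-free value.  IC50 (uM) is the half-maximal inhibitory
concentration and nH the Hill coefficient; both are measured per current.

Two table modes exist:

* ``computed`` evaluates the Hill expression for any dose from the IC50/nH
  registry (``data/drugs.csv``);
* ``verbatim`` returns the published amiodarone percentages at the two
  therapeutic doses (1 and 3 uM) exactly as printed
  (``data/amiodarone_verbatim.csv``).  This is the package default for
  reproduction runs, because the printed percentages for the non-unity Hill
  rows cannot be regenerated exactly from the rounded IC50/nH constants
  (they differ in the second decimal, presumably from unrounded Hill
  coefficients used by the original authors).

Block factors are expressed against the conductance symbols of
:class:`~sqt3sim.ionic_cell.CellParams` (G_Kr, G_Na, P_NaK, G_CaL, P_NaCa,
G_Ks); :func:`apply_drug` rescales a parameter set accordingly.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError, MappingError, UnsupportedDoseError
from .ionic_cell import CellParams

__all__ = [
    "BlockMode",
    "DrugSpec",
    "BlockTable",
    "block_conductivity",
    "load_drug",
    "build_block_table",
    "apply_drug",
    "AMIODARONE",
]

#: current id -> (conductance symbol, CellParams attribute)
CURRENT_TO_CONDUCTANCE = {
    "I_Kr": ("G_Kr", "g_kr"),
    "I_Na": ("G_Na", "g_na"),
    "I_NaK": ("P_NaK", "p_nak"),
    "I_CaL": ("G_CaL", "g_cal"),
    "I_NaCa": ("P_NaCa", "k_naca"),
    "I_Ks": ("G_Ks", "g_ks"),
}
CONDUCTANCE_TO_ATTR = {sym: attr for sym, attr in CURRENT_TO_CONDUCTANCE.values()}


class BlockMode(enum.Enum):
    COMPUTED = "computed"
    VERBATIM = "verbatim"


@dataclass(frozen=True)
class DrugSpec:
    """Per-current IC50 (uM) and Hill coefficients of one drug."""

    name: str
    entries: tuple[tuple[str, float, float], ...]  # (current id, ic50, nh)

    def __post_init__(self):
        for cur, ic50, nh in self.entries:
            if ic50 <= 0:
                raise DomainError(f"IC50 must be positive ({cur})")
            if nh <= 0:
                raise DomainError(f"Hill coefficient must be positive ({cur})")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["current", "ic50_uM", "nh"]
        ).assign(drug=self.name)


@dataclass(frozen=True)
class BlockTable:
    """Fraction of each conductance remaining at one dose."""

    drug: str
    dose_uM: float
    factors: tuple[tuple[str, float], ...]  # (conductance symbol, fraction)
    mode: BlockMode

    def __post_init__(self):
        for sym, f in self.factors:
            if not 0.0 < f <= 1.0:
                raise DomainError(f"block factor for {sym} outside (0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dict(self.factors)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.factors, columns=["conductance", "fraction_remaining"])
        df.insert(0, "dose_uM", self.dose_uM)
        df.insert(0, "drug", self.drug)
        df["percent_remaining"] = 100.0 * df["fraction_remaining"]
        df["mode"] = self.mode.value
        return df


def block_conductivity(dose: float, ic50: float, nh: float) -> float:
    """Fraction of conductance remaining at ``dose`` (uM); 1 at dose 0."""
    if dose < 0:
        raise DomainError("dose must be non-negative")
    if ic50 <= 0 or nh <= 0:
        raise DomainError("IC50 and nH must be positive")
    if dose == 0.0:
        return 1.0
    return 1.0 / (1.0 + (dose / ic50) ** nh)


def _data_path(name):
    return importlib.resources.files("sqt3sim") / "data" / name


def load_drug(name: str = "amiodarone") -> DrugSpec:
    """Load a drug's IC50/nH entries from the packaged registry."""
    df = pd.read_csv(_data_path("drugs.csv"))
    df = df[df["drug"] == name]
    if df.empty:
        raise MappingError(f"unknown drug {name!r}")
    return DrugSpec(
        name=name,
        entries=tuple(
            (r.current, float(r.ic50_uM), float(r.nh)) for r in df.itertuples()
        ),
    )


def _verbatim_table(drug: str, dose: float) -> BlockTable:
    df = pd.read_csv(_data_path(f"{drug}_verbatim.csv"))
    sub = df[df["dose_uM"] == dose]
    if sub.empty:
        doses = sorted(df["dose_uM"].unique())
        raise UnsupportedDoseError(
            f"verbatim tables for {drug} exist only at doses {doses} uM, "
            f"not {dose} uM"
        )
    return BlockTable(
        drug=drug,
        dose_uM=float(dose),
        factors=tuple(
            (r.conductance, float(r.percent_remaining) / 100.0)
            for r in sub.itertuples()
        ),
        mode=BlockMode.VERBATIM,
    )


def build_block_table(
    drug: DrugSpec | str,
    dose: float,
    mode: BlockMode | str = BlockMode.VERBATIM,
) -> BlockTable:
    """Per-conductance scaling factors of ``drug`` at ``dose`` (uM)."""
    mode = BlockMode(mode) if not isinstance(mode, BlockMode) else mode
    name = drug if isinstance(drug, str) else drug.name
    if dose < 0:
        raise DomainError("dose must be non-negative")
    if mode is BlockMode.VERBATIM:
        return _verbatim_table(name, dose)
    spec = load_drug(name) if isinstance(drug, str) else drug
    factors = []
    for cur, ic50, nh in spec.entries:
        if cur not in CURRENT_TO_CONDUCTANCE:
            raise MappingError(f"current {cur!r} has no conductance mapping")
        sym, _ = CURRENT_TO_CONDUCTANCE[cur]
        factors.append((sym, block_conductivity(dose, ic50, nh)))
    return BlockTable(name, float(dose), tuple(factors), BlockMode.COMPUTED)


def apply_drug(p: CellParams, table: BlockTable | None) -> CellParams:
    """Return a parameter set with the table's conductances rescaled.

    Conductances absent from the table are untouched; an empty or None
    table returns the parameters unchanged.
    """
    if table is None:
        return p
    updates: dict[str, float] = {}
    for sym, frac in table.factors:
        attr = CONDUCTANCE_TO_ATTR.get(sym)
        if attr is None:
            raise MappingError(f"conductance {sym!r} not present in CellParams")
        updates[attr] = getattr(p, attr) * frac
    return p.replace(**updates) if updates else p


#: convenience presets for the two therapeutic amiodarone doses
def AMIODARONE(dose: float, mode: BlockMode | str = BlockMode.VERBATIM) -> BlockTable:
    return build_block_table("amiodarone", dose, mode)
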