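"""Shared fixtures: cached expensive simulations.

Everything heavy (paced APs, fiber beats, vulnerability windows) is cached
per parameter combination so that unit, property and acceptance tests can
share one simulation.
"""

import functools

import numpy as np
import pytest

from sqt3sim.cell_protocols import StimulusProtocol, measure_apd90, pace
from sqt3sim.drug_block import AMIODARONE, apply_drug
from sqt3sim.ionic_cell import CellParams
from sqt3sim import tissue1d as t1


def cell_params(cell_type="EPI", variant="WT", dose=0.0):
    p = CellParams.default(cell_type, variant)
    if dose:
        p = apply_drug(p, AMIODARONE(dose))
    return p


@functools.lru_cache(maxsize=None)
def paced_trace(cell_type="EPI", variant="WT", dose=0.0, n_beats=10, bcl=800.0):
    return pace(cell_params(cell_type, variant, dose),
                StimulusProtocol(n_beats=n_beats, bcl=bcl))


@functools.lru_cache(maxsize=None)
def apd90(cell_type="EPI", variant="WT", dose=0.0, n_beats=10, bcl=800.0):
    return measure_apd90(paced_trace(cell_type, variant, dose, n_beats, bcl))


@functools.lru_cache(maxsize=None)
def fiber_field(variant="WT", dose=0.0, n_beats=3, duration_ms=None,
                diffusion=None):
    kw = {}
    if diffusion is not None:
        kw["diffusion_cm2_ms"] = diffusion
    cfg = t1.FiberConfig(**kw)
    table = AMIODARONE(dose) if dose else None
    f = t1.build_fiber(cfg, drug_table=table, variant=variant)
    return t1.simulate_fiber(
        f, StimulusProtocol(n_beats=n_beats), duration_ms=duration_ms
    )


@functools.lru_cache(maxsize=None)
def fiber_model(variant="WT", dose=0.0):
    table = AMIODARONE(dose) if dose else None
    return t1.build_fiber(drug_table=table, variant=variant)


@functools.lru_cache(maxsize=None)
def vulnerability_window(variant, dose, site, lo=285.0, hi=470.0):
    return t1.vulnerable_window(
        fiber_model(variant, dose), site, (lo, hi), method="bisect"
    )


@pytest.fixture(scope="session")
def cv_wt():
    fld = fiber_field("WT", n_beats=1, duration_ms=150.0)
    return t1.measure_cv(fld)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170607)
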