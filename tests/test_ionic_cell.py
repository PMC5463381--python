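"""Single-cell model: oracle agreement, rest stability, gating invariants."""

import numpy as np
import pytest

import rhs_oracle
from conftest import apd90, cell_params
from sqt3sim import _kernel
from sqt3sim.cell_protocols import StimulusProtocol, measure_apd90, pace
from sqt3sim.errors import DomainError, InstabilityError, IntegrityError
from sqt3sim.ionic_cell import (
    CellParams,
    CellState,
    Ik1Params,
    Ik1Variant,
    compute_currents,
    ik1_current,
    initial_state,
    resting_state,
    step_cell,
    variant_scale_shift,
)

VARIANTS = ["WT", "WT-D172N", "D172N"]
CELL_TYPES = ["ENDO", "MIDDLE", "EPI"]


def random_state(rng) -> CellState:
    """Physiologically plausible random state."""
    vals = np.empty(_kernel.NSTATE)
    vals[0] = rng.uniform(-90.0, 40.0)
    vals[1:16] = rng.uniform(0.0, 1.0, 15)
    vals[16] = rng.uniform(1e-5, 1e-3)    # cai
    vals[17] = rng.uniform(0.5, 4.0)      # casr
    vals[18] = rng.uniform(1e-5, 1e-2)    # cass
    vals[19] = rng.uniform(5.0, 15.0)     # nai
    vals[20] = rng.uniform(120.0, 150.0)  # ki
    return CellState(vals)


@pytest.mark.parametrize("cell_type,variant", [
    ("EPI", "WT"), ("ENDO", "D172N"), ("MIDDLE", "WT-D172N"),
])
def test_currents_match_independent_oracle(rng, cell_type, variant):
    """Hand-coded second implementation agrees to 1e-9 relative."""
    p = CellParams.default(cell_type, variant)
    pd = rhs_oracle.cell_params_to_dict(p)
    for _ in range(100):
        s = random_state(rng)
        mine = compute_currents(s, p).as_dict()
        ref = rhs_oracle.currents(rhs_oracle.state_to_dict(s), pd)
        for name, val in ref.items():
            assert mine[name] == pytest.approx(
                val, rel=1e-9, abs=1e-9
            ), f"{name} at V={s.v:.2f}"


def test_breakdown_sums_to_total(rng):
    p = CellParams.default()
    for _ in range(20):
        cb = compute_currents(random_state(rng), p)
        parts = cb.as_array()[:-1]
        assert cb.i_ion == pytest.approx(parts.sum(), rel=1e-12, abs=1e-12)


def test_compute_currents_rejects_nan():
    s = initial_state()
    s.values[0] = np.nan
    with pytest.raises(IntegrityError):
        compute_currents(s, CellParams.default())


def test_resting_state_is_quiescent():
    """After 10 s unstimulated settling the net current nearly vanishes."""
    p = CellParams.default("EPI", "WT")
    rest = resting_state(p)
    assert abs(compute_currents(rest, p).i_ion) < 0.05
    # and one further step barely moves the voltage
    nxt = step_cell(rest, p, i_stim=0.0)
    assert abs(nxt.v - rest.v) < 1e-3


def test_single_step_and_instability_error():
    p = CellParams.default()
    s = resting_state(p)
    with pytest.raises(DomainError):
        step_cell(s, p, dt=0.0)
    bad = s.copy()
    with pytest.raises(InstabilityError) as exc:
        step_cell(bad, p, i_stim=-1e6)
    assert exc.value.t_ms is not None


def test_paced_beat_has_overshoot():
    tr = pace(CellParams.default("EPI", "WT"), StimulusProtocol(n_beats=1))
    assert tr.v.max() > 0.0
    assert tr.v[0] < -80.0


def test_pace_without_beats_stays_at_rest():
    tr = pace(CellParams.default(), StimulusProtocol(n_beats=0))
    assert tr.stim_onsets == ()
    assert np.ptp(tr.v) < 0.5


def test_pace_deterministic():
    a = pace(CellParams.default("ENDO", "WT"), StimulusProtocol(n_beats=2))
    b = pace(CellParams.default("ENDO", "WT"), StimulusProtocol(n_beats=2))
    assert np.array_equal(a.v, b.v)


@pytest.mark.parametrize("variant", VARIANTS)
@pytest.mark.parametrize("cell_type", CELL_TYPES)
def test_gates_and_concentrations_stay_physical(cell_type, variant):
    """Gates remain in [0,1] and concentrations positive while pacing."""
    p = cell_params(cell_type, variant)
    P = p.to_array()
    s = resting_state(p).values.copy()
    dt = 0.02
    n_steps = int(round(2 * 800.0 / dt))
    stims = np.array([0, int(round(800.0 / dt))], np.int64)
    snap_steps = np.arange(0, n_steps, int(round(25.0 / dt)), dtype=np.int64)
    snaps = np.empty((len(snap_steps), _kernel.NSTATE))
    v_rec = np.empty(n_steps + 1)
    status = _kernel.integrate_cell(
        s, P, dt, n_steps, stims, 50, -52.0, 1, v_rec, snap_steps, snaps, True
    )
    assert status == -1
    for row in snaps:
        CellState(row).validate()   # raises if a gate or concentration leaves range


def test_apd90_cell_type_ordering():
    """Mid-myocardial cells have the longest APD in every genotype."""
    for variant in VARIANTS:
        mid = apd90("MIDDLE", variant)
        epi = apd90("EPI", variant)
        endo = apd90("ENDO", variant)
        assert mid > epi >= endo - 1e-9, (variant, mid, epi, endo)


def test_apd90_variant_ordering():
    """Gain-of-function I_K1 shortens the AP: WT > WT-D172N > D172N."""
    for ct in CELL_TYPES:
        a, b, c = (apd90(ct, v) for v in VARIANTS)
        assert a > b > c, (ct, a, b, c)


def test_time_step_convergence():
    """Halving dt changes APD90 by < 1 ms."""
    p = CellParams.default("EPI", "WT")
    proto = StimulusProtocol(n_beats=3)
    a = measure_apd90(pace(p, proto, dt=0.02))
    b = measure_apd90(pace(p, proto, dt=0.01))
    assert abs(a - b) < 1.0


def test_rush_larsen_agrees_with_forward_euler_gates():
    """At a small time step the exponential and explicit gate integrators
    converge to the same APD90.

    dt must sit below twice the fastest gate time constant for plain
    forward Euler to be stable at all; tau_m of this model reaches
    ~0.0009 ms near rest, so the comparison runs at dt = 0.0005 ms.
    """
    p = CellParams.default("EPI", "WT-D172N")
    proto = StimulusProtocol(n_beats=2)
    a = measure_apd90(pace(p, proto, dt=0.0005, rush_larsen=True))
    b = measure_apd90(pace(p, proto, dt=0.0005, rush_larsen=False))
    assert abs(a - b) < 0.5


def test_ik1_zero_at_reversal_potential():
    for variant in Ik1Variant:
        p = Ik1Params().for_variant(variant)
        ek = _kernel.RTONF * np.log(5.4 / 138.3)
        assert ik1_current(ek, 138.3, 5.4, p) == pytest.approx(0.0, abs=1e-12)


def test_ik1_domain_errors():
    with pytest.raises(DomainError):
        ik1_current(-80.0, 0.0, 5.4, Ik1Params())
    with pytest.raises(DomainError):
        ik1_current(-80.0, 138.3, -1.0, Ik1Params())
    with pytest.raises(DomainError):
        Ik1Params(g_k1=-1.0)


def test_variant_registry_peak_ordering():
    """Peak-current scaling: WT < WT-D172N < D172N (gain of function)."""
    pk = {}
    v_grid = np.arange(-120.0, 20.1, 0.5)
    for variant in Ik1Variant:
        p = Ik1Params().for_variant(variant)
        cur = [ik1_current(v, 138.3, 5.4, p) for v in v_grid]
        pk[variant] = max(cur)
    assert pk[Ik1Variant.WT] < pk[Ik1Variant.WT_D172N] < pk[Ik1Variant.D172N]


def test_state_csv_roundtrip(tmp_path):
    s = resting_state(CellParams.default("MIDDLE", "D172N"))
    path = tmp_path / "state.csv"
    s.to_csv(path)
    s2 = CellState.from_csv(path)
    np.testing.assert_array_equal(s.values, s2.values)


def test_cell_params_validation():
    with pytest.raises(DomainError):
        CellParams(g_na=-1.0)
    # every drug-rescaled symbol appears exactly once on CellParams
    p = CellParams.default()
    from sqt3sim.drug_block import CONDUCTANCE_TO_ATTR

    for attr in CONDUCTANCE_TO_ATTR.values():
        assert hasattr(p, attr)


def test_registry_values_match_committed_file():
    scale, shift, slope = variant_scale_shift(Ik1Variant.D172N)
    assert shift > 0 and 0 < slope < 0.1 and scale > 1
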