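"""Pacing biomarkers: APD90 geometry, ERP search, restitution, delta-V."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import apd90, cell_params, paced_trace
from sqt3sim.cell_protocols import (
    ApTrace,
    StimulusProtocol,
    _bank,
    delta_v,
    max_slope,
    measure_apd90,
    measure_erp,
    pace,
    restitution,
)
from sqt3sim.errors import AlignmentError, DomainError, MeasurementError


def trapezoid_trace(dt=0.05, t_on=20.0, rise=2.0, plateau=150.0, fall=40.0,
                    v0=-80.0, v1=20.0, total=400.0):
    """Piecewise-analytic AP surrogate with known APD90 geometry.

    The upstroke is quadratic (strictly increasing slope), so the maximum
    dV/dt sits at the end of the rise and APD90 = plateau + 0.9 * fall up
    to grid quantization.
    """
    t = np.arange(0.0, total, dt)
    v = np.full_like(t, v0)
    r = (t >= t_on) & (t < t_on + rise)
    v[r] = v0 + (v1 - v0) * ((t[r] - t_on) / rise) ** 2
    p = (t >= t_on + rise) & (t < t_on + rise + plateau)
    v[p] = v1
    f = (t >= t_on + rise + plateau) & (t < t_on + rise + plateau + fall)
    v[f] = v1 - (v1 - v0) * (t[f] - (t_on + rise + plateau)) / fall
    return ApTrace(t, v, (t_on,), dt)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    plateau=st.floats(50.0, 250.0),
    fall=st.floats(10.0, 120.0),
    rise=st.floats(1.0, 5.0),
)
def test_apd90_of_trapezoid_matches_closed_form(plateau, fall, rise):
    """APD90 of a trapezoid = rise + plateau + 90% of the falling edge."""
    dt = 0.05
    tr = trapezoid_trace(dt=dt, rise=rise, plateau=plateau, fall=fall)
    expected = plateau + 0.9 * fall
    got = measure_apd90(tr)
    # grid quantization of the corners bounds the error
    assert got == pytest.approx(expected, abs=3 * dt)


def test_apd90_requires_an_action_potential():
    t = np.arange(0, 100, 0.1)
    flat = ApTrace(t, np.full_like(t, -85.0), (10.0,), 0.1)
    with pytest.raises(MeasurementError):
        measure_apd90(flat)
    with pytest.raises(MeasurementError):
        measure_apd90(ApTrace(t, np.full_like(t, -85.0), (), 0.1))


def test_apd90_measures_s2_beat_when_present():
    p = cell_params("EPI", "WT")
    tr = pace(p, StimulusProtocol(n_beats=2, s2_coupling=400.0))
    apd_s2 = measure_apd90(tr)            # last stimulus = S2
    apd_s1 = measure_apd90(tr, stim_index=0)
    assert apd_s2 < apd_s1                # premature beat is shorter


def test_erp_bisection_equals_exhaustive_scan():
    """The 5 ms + bisection search equals a brute-force 0.5 ms scan."""
    p = cell_params("EPI", "WT-D172N")
    proto = StimulusProtocol(n_beats=5)
    erp = measure_erp(p, proto)
    bank = _bank(p, proto, 0.02, horizon=proto.bcl + 100.0)
    c = 50.0
    while not bank.s2_response_is_ap(c):
        c += 0.5
    assert erp == pytest.approx(c, abs=0.51)
    assert erp > 50.0


def test_erp_sane_and_drug_prolongs_it():
    """ERP is finite, within 50 ms of APD90, and amiodarone increases it."""
    proto = StimulusProtocol(n_beats=5)
    for variant in ("WT-D172N", "D172N"):
        erp0 = measure_erp(cell_params("EPI", variant), proto)
        a0 = apd90("EPI", variant)
        assert erp0 >= a0 - 50.0
        for dose in (1.0, 3.0):
            erp_d = measure_erp(cell_params("EPI", variant, dose), proto)
            assert erp_d > erp0, (variant, dose, erp_d, erp0)


def test_amiodarone_prolongs_apd():
    for variant in ("WT-D172N", "D172N"):
        base = apd90("EPI", variant)
        for dose in (1.0, 3.0):
            assert apd90("EPI", variant, dose) > base


COUPLINGS = tuple(np.arange(290.0, 641.0, 25.0))


def test_apd_restitution_monotone_in_di():
    """APD-R is non-decreasing in DI for all genotypes and doses, with a
    finite positive maximal slope."""
    for variant in ("WT-D172N", "D172N"):
        for dose in (0.0, 1.0, 3.0):
            curve = restitution(cell_params("EPI", variant, dose), "APD-R",
                                COUPLINGS)
            assert np.all(np.diff(curve.y) >= -0.05), (variant, dose)
            assert curve.max_slope > 0


def test_flat_restitution_has_zero_slope():
    assert max_slope(np.array([100.0, 200.0, 300.0]),
                     np.array([250.0, 250.0, 250.0])) == 0.0


def test_restitution_rejects_unknown_kind():
    with pytest.raises(DomainError):
        restitution(cell_params(), "bogus", [100.0, 200.0])


def test_restitution_flags_failed_points():
    """Couplings deep inside the refractory period are excluded, not fatal."""
    curve = restitution(cell_params("EPI", "WT"), "APD-R",
                        (150.0, 400.0, 500.0))
    assert 150.0 in curve.excluded
    assert curve.x.size == 2


def test_delta_v_identities():
    a = paced_trace("ENDO", "WT-D172N")
    b = paced_trace("MIDDLE", "WT-D172N")
    series, mx = delta_v(a, b)
    anti, mx2 = delta_v(b, a)
    np.testing.assert_array_equal(series, -anti)
    assert mx == mx2 > 0
    zero, mz = delta_v(a, a)
    assert mz == 0.0 and not zero.any()


def test_delta_v_alignment_checks():
    a = paced_trace("ENDO", "WT")
    t = np.arange(0, 50, 0.02)
    b = ApTrace(t, np.zeros_like(t), (0.0,), 0.02)
    with pytest.raises(AlignmentError):
        delta_v(a, b)


def test_delta_v_reduced_by_amiodarone():
    """Transmural voltage heterogeneity shrinks under the drug."""
    base = delta_v(paced_trace("ENDO", "WT-D172N"),
                   paced_trace("MIDDLE", "WT-D172N"))[1]
    low = delta_v(paced_trace("ENDO", "WT-D172N", 1.0),
                  paced_trace("MIDDLE", "WT-D172N", 1.0))[1]
    assert low < base
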