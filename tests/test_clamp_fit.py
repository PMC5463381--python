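"""Voltage clamp, variant calibration and I-V fitting."""

import numpy as np
import pytest
from dataclasses import replace

from sqt3sim.clamp_fit import (
    ClampProtocol,
    IvCurve,
    calibrate_variants,
    fit_ik1,
    generate_synthetic_iv,
    peak_outward,
    simulate_iv,
)
from sqt3sim.errors import CalibrationError, DomainError
from sqt3sim.ionic_cell import Ik1Params, Ik1Variant


def test_default_protocol_matches_experimental_sweep():
    proto = ClampProtocol()
    assert proto.holding_mV == -60.0
    assert proto.step_mV[0] == -120.0 and proto.step_mV[-1] == 20.0
    assert len(proto.step_mV) == 29
    assert proto.step_duration_ms == 400.0


def test_reversal_potential_shared_across_variants():
    """The variant changes gain, not the zero-crossing voltage."""
    fine = ClampProtocol(step_mV=tuple(np.arange(-100.0, -70.0, 0.05)))
    crossings = {}
    for variant in Ik1Variant:
        c = simulate_iv(Ik1Params(), variant, fine)
        k = int(np.nonzero(np.diff(np.sign(c.i)))[0][0])
        crossings[variant] = c.v[k]
    vals = list(crossings.values())
    assert max(vals) - min(vals) < 0.1


def test_calibrated_fold_changes():
    cal = calibrate_variants(Ik1Params())
    pk = {v: peak_outward(simulate_iv(p))[0] for v, p in cal.items()}
    wt = pk[Ik1Variant.WT]
    assert pk[Ik1Variant.WT_D172N] / wt == pytest.approx(2.2, rel=1e-3)
    assert pk[Ik1Variant.D172N] / wt == pytest.approx(4.6, rel=1e-3)


def test_calibrated_peak_voltage_right_shifted():
    cal = calibrate_variants(Ik1Params())
    fine = ClampProtocol(step_mV=tuple(np.arange(-90.0, 0.1, 0.25)))
    v_pk = {v: peak_outward(simulate_iv(p, proto=fine))[1] for v, p in cal.items()}
    assert v_pk[Ik1Variant.D172N] > v_pk[Ik1Variant.WT]
    assert v_pk[Ik1Variant.WT_D172N] >= v_pk[Ik1Variant.WT]


def test_identity_calibration_returns_base():
    base = Ik1Params()
    cal = calibrate_variants(
        base,
        targets={Ik1Variant.WT_D172N: 1.0, Ik1Variant.D172N: 1.0},
        shapes={v: (0.0, 0.1) for v in Ik1Variant},
    )
    for p in cal.values():
        assert p.scale == pytest.approx(1.0, rel=1e-12)
        assert p.shift_mV == 0.0


def test_calibration_idempotent():
    """Re-deriving the registry from its own output changes nothing."""
    first = calibrate_variants(Ik1Params())
    second = calibrate_variants(first[Ik1Variant.WT])
    for v in Ik1Variant:
        assert second[v].scale == pytest.approx(first[v].scale, abs=1e-6)
        assert second[v].shift_mV == first[v].shift_mV


def test_calibration_matches_committed_registry():
    cal = calibrate_variants(Ik1Params())
    for variant in Ik1Variant:
        packaged = Ik1Params().for_variant(variant)
        assert cal[variant].scale == pytest.approx(packaged.scale, rel=1e-9)
        assert cal[variant].shift_mV == packaged.shift_mV
        assert cal[variant].slope == packaged.slope


def test_impossible_fold_raises():
    with pytest.raises(CalibrationError):
        calibrate_variants(
            Ik1Params(),
            targets={Ik1Variant.D172N: -2.0},
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_noiseless_parameters():
    truth = Ik1Params(scale=2.0, shift_mV=6.0, slope=0.09)
    data = simulate_iv(truth)
    init = replace(truth, scale=1.3, shift_mV=1.0)
    res = fit_ik1(data, init)
    assert res.params.scale == pytest.approx(2.0, rel=0.01)
    assert res.params.shift_mV == pytest.approx(6.0, rel=0.01)
    assert res.residual <= res.residual_init
    assert res.rmse < 1e-3


def test_fit_from_truth_converges_immediately():
    truth = Ik1Params(scale=1.5, shift_mV=4.0)
    data = simulate_iv(truth)
    res = fit_ik1(data, truth)
    assert res.residual == pytest.approx(0.0, abs=1e-12)
    assert res.params.scale == pytest.approx(1.5, rel=1e-6)


def test_fit_recovers_constructed_scaling():
    """Data scaled by 2.2 fits a 2.2-fold larger conductance scale."""
    base = Ik1Params()
    data = simulate_iv(base)
    scaled = IvCurve(data.v, 2.2 * data.i)
    res = fit_ik1(scaled, replace(base, scale=1.4), free=("scale",))
    assert res.params.scale == pytest.approx(2.2, rel=0.01)


def test_fit_parameter_recovery_under_noise():
    """Recovering the packaged homozygous-variant parameters: median
    |error| < 5% over 20 seeded replicates at 5%-of-peak noise."""
    truth = Ik1Params().for_variant(Ik1Variant.D172N)
    peak, _ = peak_outward(simulate_iv(truth))
    errs = []
    for seed in range(20):
        data = generate_synthetic_iv(truth, noise_sd=0.05 * peak, seed=seed)
        res = fit_ik1(data, replace(truth, scale=2.0, shift_mV=3.0))
        errs.append([
            abs(res.params.scale / truth.scale - 1.0),
            abs(res.params.shift_mV / truth.shift_mV - 1.0),
        ])
    med = np.median(np.array(errs), axis=0)
    assert np.all(med < 0.05), med


def test_fit_input_validation():
    data = simulate_iv(Ik1Params())
    with pytest.raises(DomainError):
        fit_ik1(data, Ik1Params(), free=("bogus",))
    tiny = IvCurve(data.v[:1], data.i[:1])
    with pytest.raises(DomainError):
        fit_ik1(tiny, Ik1Params())


def test_fit_summary_mentions_free_parameters():
    data = simulate_iv(Ik1Params(scale=1.2))
    res = fit_ik1(data, Ik1Params())
    text = res.summary()
    assert "scale" in text and "SSR" in text


# ---------------------------------------------------------------------------
# synthetic data generator
# ---------------------------------------------------------------------------

def test_synthetic_iv_noise_free_equals_model():
    p = Ik1Params().for_variant(Ik1Variant.D172N)
    a = generate_synthetic_iv(p, noise_sd=0.0)
    b = simulate_iv(p)
    np.testing.assert_array_equal(a.i, b.i)


def test_synthetic_iv_seed_reproducible():
    p = Ik1Params()
    a = generate_synthetic_iv(p, noise_sd=0.1, seed=42)
    b = generate_synthetic_iv(p, noise_sd=0.1, seed=42)
    np.testing.assert_array_equal(a.i, b.i)
    c = generate_synthetic_iv(p, noise_sd=0.1, seed=43)
    assert not np.array_equal(a.i, c.i)


def test_synthetic_iv_noise_magnitude():
    """Sample sd of (data - model) respects chi-square bounds at n = 29."""
    p = Ik1Params()
    model = simulate_iv(p)
    resid = generate_synthetic_iv(p, noise_sd=0.1, seed=7).i - model.i
    assert 0.05 < resid.std(ddof=1) < 0.2


def test_iv_csv_roundtrip(tmp_path):
    c = simulate_iv(Ik1Params())
    path = tmp_path / "iv.csv"
    c.to_csv(path)
    c2 = IvCurve.from_csv(path)
    np.testing.assert_allclose(c.i, c2.i)
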