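"""Transmural strand: geometry, propagation, pseudo-ECG, vulnerability."""

import numpy as np
import pytest

import rhs_oracle
from conftest import fiber_field, fiber_model, vulnerability_window
from sqt3sim import tissue1d as t1
from sqt3sim.cell_protocols import StimulusProtocol
from sqt3sim.errors import ConfigError, MeasurementError
from sqt3sim.ionic_cell import CellParams, CellType


def test_fiber_config_validation():
    with pytest.raises(ConfigError):
        t1.FiberConfig(nx=99)                       # nx*dx != length
    with pytest.raises(ConfigError):
        t1.FiberConfig(proportions=(30, 30, 30))    # not 100%
    with pytest.raises(ConfigError):
        t1.FiberConfig(dt_ms=1.0)                   # D*dt/dx^2 >= 0.5
    with pytest.raises(ConfigError):
        t1.FiberConfig(proportions=(25.5, 34.5, 40.0))  # fractional nodes


def test_default_fiber_layout():
    f = t1.build_fiber()
    assert f.config.region_nodes == (25, 35, 40)
    types = f.node_types
    assert types[:25] == [CellType.ENDO] * 25
    assert types[25:60] == [CellType.MIDDLE] * 35
    assert types[60:] == [CellType.EPI] * 40
    base = f.config.diffusion_cm2_ms / f.config.dx_cm**2
    # exactly one reduced face, at the MIDDLE-EPI junction, scaled by 1/5
    assert f.w[f.junction_face] == pytest.approx(base / 5.0, rel=1e-12)
    others = np.delete(f.w, f.junction_face)
    np.testing.assert_allclose(others, base)


def test_homogeneous_fiber_has_uniform_coupling():
    p = {ct: CellParams.default("EPI", "WT") for ct in CellType}
    f = t1.build_fiber(t1.FiberConfig(proportions=(0.0, 0.0, 100.0)), params=p)
    np.testing.assert_allclose(f.w, f.w[0])


def test_unstimulated_fiber_stays_at_rest():
    f = t1.build_fiber(variant="WT")
    fld = t1.simulate_fiber(f, StimulusProtocol(n_beats=0), duration_ms=50.0)
    assert np.ptp(fld.v) < 1.0
    assert np.isnan(t1.measure_cv(fld))     # no propagation -> failure code


def test_activation_spreads_monotonically_from_endo():
    fld = fiber_field("WT", n_beats=1, duration_ms=150.0)
    act = t1.activation_times(fld)
    seg = act[3:59]          # stimulus face to just before the junction
    assert np.all(np.isfinite(seg))
    assert np.all(np.diff(seg) > 0)


def test_cv_near_published_value(cv_wt):
    assert cv_wt == pytest.approx(52.0, abs=2.0)


def test_cv_scales_as_sqrt_of_diffusion(cv_wt):
    """Cable theory: quartering D halves the conduction velocity.

    The space constant shrinks with sqrt(D), so the coarse-grid
    discretization error would not cancel between the two runs; the
    quarter-D fiber therefore uses a half-width grid (matched dx/lambda).
    """
    cfg = t1.FiberConfig(dx_mm=0.075, nx=200, diffusion_cm2_ms=0.0002)
    f = t1.build_fiber(cfg, variant="WT")
    fld = t1.simulate_fiber(f, StimulusProtocol(n_beats=1), duration_ms=250.0)
    slow = t1.measure_cv(fld, lo_node=20, hi_node=110)
    assert slow == pytest.approx(cv_wt / 2.0, rel=0.05)


def test_cv_nearly_insensitive_to_ik1_variant(cv_wt):
    """The variant targets repolarization: CV moves only a few percent
    (the enlarged inward rectifier loads the upstroke foot slightly)."""
    cv_hom = t1.measure_cv(fiber_field("D172N", n_beats=1, duration_ms=150.0))
    assert abs(cv_hom - cv_wt) < 3.0


def test_pseudo_ecg_zero_for_uniform_field():
    fld = fiber_field("WT", n_beats=1, duration_ms=150.0)
    uniform = t1.SpaceTimeField(
        fld.t, np.full_like(fld.v, -20.0), fld.node_types, fld.config, (0.0,)
    )
    x = np.arange(fld.config.nx) * fld.config.dx_cm
    phie = rhs_oracle.pseudo_ecg_oracle(
        uniform.t[:5], uniform.v[:5], x, -2.0, 0.24
    )
    np.testing.assert_allclose(phie, 0.0, atol=1e-15)
    with pytest.raises(MeasurementError):
        t1.pseudo_ecg(uniform)      # no T wave above threshold either


def test_pseudo_ecg_matches_quadrature_oracle():
    """Discretized far-field integral agrees with the independent
    evaluation to 1e-6 relative."""
    fld = fiber_field("WT-D172N", n_beats=3)
    ecg = t1.pseudo_ecg(fld)
    cfg = fld.config
    x = np.arange(cfg.nx) * cfg.dx_cm
    ref = rhs_oracle.pseudo_ecg_oracle(
        fld.t, fld.v, x, -cfg.electrode_cm, cfg.alpha_mm / 10.0
    )
    scale = np.abs(ref).max()
    assert np.abs(ecg.phie - ref).max() / scale < 1e-6


def test_ecg_polarity_and_twave_metrics():
    """ENDO->EPI propagation, ENDO-side electrode: negative QRS, positive T."""
    fld = fiber_field("WT-D172N", n_beats=3)
    ecg = t1.pseudo_ecg(fld)
    i_qrs = int(np.searchsorted(fld.t, t1.QRS_END_MS))
    assert ecg.phie[:i_qrs].min() < -0.2        # negative QRS
    assert ecg.t_amp_mV > 0.05                  # positive T wave
    assert ecg.t_end_ms > ecg.t_peak_ms > t1.QRS_END_MS
    assert ecg.qt_ms == pytest.approx(ecg.t_end_ms - ecg.q_onset_ms)


def test_qt_ordering_and_drug_response():
    """QT(WT) > QT(het) > QT(hom); amiodarone prolongs QT in both mutants."""
    qt = {}
    for variant in ("WT", "WT-D172N", "D172N"):
        qt[variant] = t1.pseudo_ecg(fiber_field(variant, n_beats=3)).qt_ms
    assert qt["WT"] > qt["WT-D172N"] > qt["D172N"]
    for variant in ("WT-D172N", "D172N"):
        base = qt[variant]
        for dose in (1.0, 3.0):
            drugged = t1.pseudo_ecg(fiber_field(variant, dose, n_beats=3)).qt_ms
            assert drugged > base, (variant, dose)


def test_qt_alpha_sensitivity_bounded():
    """Scale-free T-end threshold (5% of T peak) stays within a few ms of
    the absolute criterion, bounding the strand-radius dependence."""
    fld = fiber_field("WT-D172N", n_beats=3)
    qt_abs = t1.pseudo_ecg(fld).qt_ms
    qt_rel = t1.pseudo_ecg(fld, relative_threshold=0.05).qt_ms
    assert abs(qt_abs - qt_rel) < 6.0


def test_t_wave_amplitude_directions():
    """Mutants raise the T wave; amiodarone lowers it again."""
    amp = lambda v, d=0.0: t1.pseudo_ecg(fiber_field(v, d, n_beats=3)).t_amp_mV
    assert amp("WT-D172N") > amp("WT")
    assert amp("D172N") > amp("WT")
    for variant in ("WT-D172N", "D172N"):
        assert amp(variant, 1.0) < amp(variant)
        assert amp(variant, 3.0) < amp(variant)


def test_apd_profile_flat_inside_homogeneous_fiber():
    p = {ct: CellParams.default("EPI", "WT") for ct in CellType}
    f = t1.build_fiber(t1.FiberConfig(junction_factor=1.0), params=p)
    fld = t1.simulate_fiber(f, StimulusProtocol(n_beats=1), duration_ms=500.0)
    apd, grad, gmax, _ = t1.apd_profile(fld)
    # clear of the no-flux ends, whose electrotonic APD perturbation
    # reaches ~2 mm into the strand
    interior = np.abs(grad[15:85])
    assert np.all(interior < 1.0)


def test_apd_dispersion_peaks_at_junction_and_drug_reduces_it():
    fld = fiber_field("WT-D172N", n_beats=3)
    apd, grad, gmax, node = t1.apd_profile(fld)
    junction = fiber_model("WT-D172N").junction_face
    assert abs(node - junction) <= 2
    _, _, gmax_drug, _ = t1.apd_profile(fiber_field("WT-D172N", 1.0, n_beats=3))
    assert gmax_drug < gmax


def test_vulnerable_window_scan_matches_bisection():
    """Edge bisection reproduces the exhaustive 0.5 ms scan."""
    f = fiber_model("WT")
    scan = t1.vulnerable_window(f, "ENDO", (330.0, 350.0), method="scan")
    bis = t1.vulnerable_window(f, "ENDO", (330.0, 350.0), method="bisect")
    assert not scan.multi_interval
    assert scan.window_start == pytest.approx(bis.window_start, abs=0.51)
    assert scan.window_end == pytest.approx(bis.window_end, abs=0.51)
    assert scan.width > 0


def test_vulnerability_outcomes_partition_the_scan():
    f = fiber_model("WT")
    res = t1.vulnerable_window(f, "ENDO", (330.0, 350.0), method="scan")
    allowed = {"bidirectional block", "unidirectional block",
               "bidirectional conduction"}
    assert set(res.outcomes.values()) <= allowed
    times = sorted(res.outcomes)
    assert times[0] == 330.0 and times[-1] == 350.0


def test_vulnerable_windows_exist_for_all_genotypes():
    """Every genotype shows a finite unidirectional-block window at both
    premature-stimulus sites, and the mutants are at least as vulnerable
    as wild type at the same site."""
    widths = {}
    for variant in ("WT", "WT-D172N", "D172N"):
        for site in ("ENDO", "EPI"):
            vw = vulnerability_window(variant, 0.0, site)
            assert vw.window_start is not None, (variant, site)
            assert vw.width > 0
            widths[variant, site] = vw.width
    for site in ("ENDO", "EPI"):
        assert widths["D172N", site] > widths["WT", site]
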