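"""Run configuration: validated YAML scenarios and the pipeline runner.

A scenario file names one pipeline (cell APD, drug table, clamp I-V,
restitution, fiber CV, pseudo-ECG, vulnerability window or 2D re-entry)
together with the genotype, drug condition, protocol, geometry and
numerics blocks.  Defaults reproduce the study conditions: dt = 0.02 ms,
dx = 0.15 mm, D = 8e-4 cm^2/ms, BCL = 800 ms and a -52 pA/pF, 1 ms
stimulus.  Unknown keys are rejected and the explicit-scheme stability
bound is enforced at load time.  All physical constants live here, in the
packaged data files, or in the dataclass defaults of the physics modules -
never inline in pipeline code.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pydantic
import yaml

from . import __version__
from .errors import ConfigError

log = logging.getLogger(__name__)


class _Base(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid", frozen=True)


class DrugConfig(_Base):
    name: str = "amiodarone"
    dose_uM: float = pydantic.Field(0.0, ge=0.0)
    mode: Literal["verbatim", "computed"] = "verbatim"


class ProtocolConfig(_Base):
    amplitude_pApF: float = -52.0
    duration_ms: float = pydantic.Field(1.0, gt=0.0)
    bcl_ms: float = pydantic.Field(800.0, gt=0.0)
    n_beats: int = pydantic.Field(10, ge=0)
    s2_coupling_ms: Optional[float] = None


class GeometryConfig(_Base):
    length_mm: float = 15.0
    width_mm: float = 75.0          # 2D only
    proportions: tuple[float, float, float] = (25.0, 35.0, 40.0)
    junction_factor: float = pydantic.Field(0.2, gt=0.0, le=1.0)
    electrode_cm: float = 2.0
    alpha_mm: float = 2.4
    s2_site: Literal["ENDO", "EPI"] = "ENDO"
    s2_time_ms: Optional[float] = None
    s2_length_mm: Optional[float] = None


class NumericsConfig(_Base):
    dt_ms: float = pydantic.Field(0.02, gt=0.0)
    dx_mm: float = pydantic.Field(0.15, gt=0.0)
    diffusion_cm2_ms: float = pydantic.Field(0.0008, gt=0.0)
    horizon_ms: float = pydantic.Field(1500.0, gt=0.0)

    @pydantic.model_validator(mode="after")
    def _stable(self):
        dx_cm = self.dx_mm / 10.0
        if self.diffusion_cm2_ms * self.dt_ms / dx_cm**2 >= 0.5:
            raise ValueError(
                "stability violation: D*dt/dx^2 = "
                f"{self.diffusion_cm2_ms * self.dt_ms / dx_cm**2:.3f} >= 0.5"
            )
        return self


PIPELINES = (
    "cell", "drugtable", "clamp", "fit", "restitution",
    "fiber", "ecg", "vulnerability", "reentry2d",
)


class RunConfig(_Base):
    scenario: str
    pipeline: Literal[PIPELINES]  # type: ignore[valid-type]
    variant: Literal["WT", "WT-D172N", "D172N"] = "WT"
    variants: Optional[tuple[str, ...]] = None       # matrix pipelines
    cell_type: Literal["ENDO", "MIDDLE", "EPI"] = "EPI"
    cell_types: Optional[tuple[str, ...]] = None
    drug: Optional[DrugConfig] = None
    protocol: ProtocolConfig = ProtocolConfig()
    geometry: GeometryConfig = GeometryConfig()
    numerics: NumericsConfig = NumericsConfig()
    output_dir: str = "out"
    seed: int = 0                                    # synthetic I-V only

    def drug_table(self):
        from .drug_block import build_block_table

        if self.drug is None or self.drug.dose_uM == 0.0:
            return None
        return build_block_table(self.drug.name, self.drug.dose_uM, self.drug.mode)


def load_config(path) -> RunConfig:
    """Load and validate a YAML scenario; errors name the offending key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from exc


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            json.loads(cfg.model_dump_json(exclude_none=True)), fh, sort_keys=False
        )


def _stim_protocol(cfg: RunConfig):
    from .cell_protocols import StimulusProtocol

    p = cfg.protocol
    return StimulusProtocol(
        s1_amplitude=p.amplitude_pApF,
        s1_duration=p.duration_ms,
        bcl=p.bcl_ms,
        n_beats=p.n_beats,
        s2_coupling=p.s2_coupling_ms,
    )


def _fiber_config(cfg: RunConfig):
    from .tissue1d import FiberConfig

    g, n = cfg.geometry, cfg.numerics
    nx = int(round(g.length_mm / n.dx_mm))
    return FiberConfig(
        length_mm=g.length_mm, nx=nx, dx_mm=n.dx_mm,
        diffusion_cm2_ms=n.diffusion_cm2_ms, proportions=g.proportions,
        junction_factor=g.junction_factor, electrode_cm=g.electrode_cm,
        alpha_mm=g.alpha_mm, dt_ms=n.dt_ms,
    )


def run_scenario(cfg: RunConfig, output_dir=None) -> dict:
    """Execute one pipeline; write CSV artifacts and a biomarker summary.

    Returns the biomarker dictionary (also written as
    ``<output_dir>/<scenario>_biomarkers.json``).
    """
    import pandas as pd

    from . import cell_protocols as cp
    from . import clamp_fit as cf
    from . import tissue1d as t1
    from . import tissue2d as t2
    from .ionic_cell import CellParams, Ik1Params
    from .drug_block import apply_drug

    t_start = time.time()
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = out / cfg.scenario
    table = cfg.drug_table()
    bio: dict = {"scenario": cfg.scenario, "pipeline": cfg.pipeline}

    if cfg.pipeline == "drugtable":
        df = table.as_frame() if table else pd.DataFrame()
        df.to_csv(f"{stem}_blocktable.csv", index=False)
        bio["factors_percent"] = (
            {k: 100.0 * v for k, v in table.as_dict().items()} if table else {}
        )

    elif cfg.pipeline == "cell":
        proto = _stim_protocol(cfg)
        cell_types = cfg.cell_types or (cfg.cell_type,)
        variants = cfg.variants or (cfg.variant,)
        rows = []
        for var in variants:
            for ct in cell_types:
                p = apply_drug(CellParams.default(ct, var), table)
                tr = cp.pace(p, proto, dt=cfg.numerics.dt_ms)
                apd = cp.measure_apd90(tr)
                rows.append({"variant": var, "cell_type": ct, "apd90_ms": apd})
                tr.to_frame().to_csv(
                    f"{stem}_{var}_{ct}_trace.csv", index=False
                )
        pd.DataFrame(rows).to_csv(f"{stem}_apd90.csv", index=False)
        bio["apd90_ms"] = {
            f"{r['variant']}/{r['cell_type']}": r["apd90_ms"] for r in rows
        }

    elif cfg.pipeline == "clamp":
        folds = {}
        for var in cfg.variants or ("WT", "WT-D172N", "D172N"):
            curve = cf.simulate_iv(Ik1Params(), variant=_variant(var))
            curve.to_csv(f"{stem}_{var}_iv.csv")
            folds[var] = cf.peak_outward(curve)[0]
        bio["peak_outward_pApF"] = folds
        bio["fold_vs_WT"] = {k: v / folds["WT"] for k, v in folds.items()}

    elif cfg.pipeline == "fit":
        truth = Ik1Params().for_variant(_variant(cfg.variant))
        data = cf.generate_synthetic_iv(truth, noise_sd=0.1, seed=cfg.seed)
        data.to_csv(f"{stem}_data.csv")
        res = cf.fit_ik1(data, Ik1Params(scale=1.2, shift_mV=2.0,
                                         slope=truth.slope))
        (out / f"{cfg.scenario}_fit.txt").write_text(res.summary() + "\n")
        bio["fitted"] = {
            "scale": res.params.scale, "shift_mV": res.params.shift_mV,
            "rmse_pApF": res.rmse,
        }

    elif cfg.pipeline == "restitution":
        p = apply_drug(CellParams.default(cfg.cell_type, cfg.variant), table)
        couplings = np.arange(280.0, 701.0, 30.0)
        apdr = cp.restitution(p, "APD-R", couplings, dt=cfg.numerics.dt_ms)
        pd.DataFrame({"di_ms": apdr.x, "apd90_ms": apdr.y}).to_csv(
            f"{stem}_apdr.csv", index=False
        )
        bcls = np.arange(300.0, 1001.0, 50.0)
        erpr = cp.restitution(p, "ERP-R", bcls, dt=cfg.numerics.dt_ms)
        pd.DataFrame({"bcl_ms": erpr.x, "erp_ms": erpr.y}).to_csv(
            f"{stem}_erpr.csv", index=False
        )
        bio["apdr_max_slope"] = apdr.max_slope
        bio["erpr_max_slope"] = erpr.max_slope

    elif cfg.pipeline in ("fiber", "ecg"):
        f = t1.build_fiber(_fiber_config(cfg), drug_table=table,
                           variant=cfg.variant)
        proto = _stim_protocol(cfg)
        if cfg.pipeline == "fiber":
            fld = t1.simulate_fiber(f, proto, duration_ms=min(
                cfg.numerics.horizon_ms, proto.n_beats * proto.bcl))
            pd.DataFrame(fld.v, index=fld.t).to_csv(f"{stem}_field.csv")
            bio["cv_cm_s"] = t1.measure_cv(fld)
        else:
            fld = t1.simulate_fiber(f, proto)
            ecg = t1.pseudo_ecg(fld)
            ecg.to_frame().to_csv(f"{stem}_ecg.csv", index=False)
            apd, grad, gmax, gnode = t1.apd_profile(fld)
            pd.DataFrame({"node": np.arange(apd.size), "apd90_ms": apd,
                          "grad_ms_mm": grad}).to_csv(
                f"{stem}_apd_profile.csv", index=False)
            bio.update(
                qt_ms=ecg.qt_ms, t_amp_mV=ecg.t_amp_mV,
                max_apd_gradient_ms_mm=gmax, max_gradient_node=int(gnode),
            )

    elif cfg.pipeline == "vulnerability":
        f = t1.build_fiber(_fiber_config(cfg), drug_table=table,
                           variant=cfg.variant)
        g = cfg.geometry
        t0 = g.s2_time_ms if g.s2_time_ms is not None else 300.0
        vw = t1.vulnerable_window(
            f, g.s2_site, (t0, t0 + 80.0), method="bisect"
        )
        pd.DataFrame(
            sorted(vw.outcomes.items()), columns=["s2_ms", "outcome"]
        ).to_csv(f"{stem}_outcomes.csv", index=False)
        bio.update(
            window_start_ms=vw.window_start, window_end_ms=vw.window_end,
            window_width_ms=vw.width, site=vw.site,
        )

    elif cfg.pipeline == "reentry2d":
        g, n = cfg.geometry, cfg.numerics
        scfg = t2.SheetConfig(
            lx_mm=g.length_mm, nx=int(round(g.length_mm / n.dx_mm)),
            ly_mm=g.width_mm, ny=int(round(g.width_mm / n.dx_mm)),
            dx_mm=n.dx_mm, diffusion_cm2_ms=n.diffusion_cm2_ms,
            proportions=g.proportions, junction_factor=g.junction_factor,
            horizon_ms=n.horizon_ms, dt_ms=n.dt_ms,
        )
        m = t2.build_sheet(scfg, drug_table=table, variant=cfg.variant)
        s2_time = g.s2_time_ms if g.s2_time_ms is not None else 320.0
        outc = t2.induce_reentry(m, s2_time, g.s2_length_mm)
        pd.DataFrame({"time_ms": outc.sample_t, "V_mV": outc.sample_v}).to_csv(
            f"{stem}_sample_ap.csv", index=False
        )
        pd.DataFrame([{
            "s2_time_ms": s2_time,
            "s2_length_mm": g.s2_length_mm or scfg.ly_mm,
            "outcome": outc.classification,
            "termination_ms": outc.termination_ms,
        }]).to_csv(f"{stem}_outcome.csv", index=False)
        bio["outcome"] = outc.classification
        bio["termination_ms"] = outc.termination_ms

    bio["wall_time_s"] = round(time.time() - t_start, 3)
    bio["version"] = __version__
    with open(f"{stem}_biomarkers.json", "w") as fh:
        json.dump(bio, fh, indent=2, default=float)
    log.info("scenario %s finished in %.1fs", cfg.scenario, bio["wall_time_s"])
    return bio


def _variant(name):
    from .ionic_cell import Ik1Variant

    return Ik1Variant(name)
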