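"""Reproducible scenario runner: generation -> fitting -> simulation ->
burst and fast-slow analysis.

A scenario is a YAML/JSON document validated by pydantic::

    name: burst_modulation
    seed: 42
    stages:
      - {kind: simulate, id: base, modulation: {g_M_scale: 1, g_KCa_scale: 1}}
      - {kind: burst_metrics, id: base_metrics, input: base}
      - {kind: fold_change, id: im_fold, a: base, b: both, current: I_M}

Each stage writes its artifact under the output directory and contributes a
JSON-able entry to the consolidated report.  Every stochastic stage derives
its stream from the scenario seed, so re-running a scenario reproduces the
report and all CSV artifacts byte for byte (the log, which carries wall
times, goes to the logger only).  A stage failure aborts with the stage id
in the message; artifacts of completed stages are retained.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Callable, Dict, List, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import burst as burst_mod
from . import events, fastslow, fitting, io, synth
from .model import ModelParams, Modulation, SimConfig, simulate

__all__ = ["Scenario", "Stage", "run_scenario", "load_scenario", "shipped_scenarios"]

logger = logging.getLogger(__name__)

SCENARIO_DIR = Path(__file__).parent / "scenarios"


class Stage(BaseModel):
    """One pipeline step; ``kind`` selects the handler, extra keys are the
    handler's parameters."""

    model_config = ConfigDict(extra="allow")

    kind: str
    id: Optional[str] = None

    def params(self) -> dict:
        return {k: v for k, v in self.model_dump().items() if k not in ("kind", "id")}


class Scenario(BaseModel):
    """Validated scenario document."""

    name: str
    seed: int = 0
    stages: List[Stage] = Field(default_factory=list)


def load_scenario(path: Union[str, Path]) -> Scenario:
    with open(path) as fh:
        return Scenario.model_validate(yaml.safe_load(fh))


def shipped_scenarios() -> List[Path]:
    return sorted(SCENARIO_DIR.glob("*.yaml"))


# ---------------------------------------------------------------------------
# stage handlers
# ---------------------------------------------------------------------------


class _Ctx:
    def __init__(self, scenario: Scenario, out: Path):
        self.scenario = scenario
        self.out = out
        self.objects: Dict[str, object] = {}

    def get(self, key: str):
        if key not in self.objects:
            raise KeyError(f"stage input {key!r} not produced by an earlier stage")
        return self.objects[key]


def _noise(ctx: _Ctx, p: dict) -> synth.NoiseSpec:
    return synth.NoiseSpec(
        trace_noise_sd=p.get("trace_noise_sd"),
        cell_cv=p.get("cell_cv", 0.15),
        seed=p.get("seed", ctx.scenario.seed),
    )


def _model_params(p: dict) -> ModelParams:
    return ModelParams(**p.get("params", {}))


def _stage_dose_response(ctx, sid, p):
    hill = fitting.HillFit(**p.get("hill", {"e_max": 100.0, "ec50": 9.8, "n_h": 1.0}))
    table = synth.gen_dose_response(
        hill, p.get("concentrations", [0.1, 1, 3, 10, 30, 100, 300]),
        noise=_noise(ctx, p), n_cells=p.get("n_cells", 10))
    ctx.objects[sid] = table
    io.write_dose_table(table, ctx.out / f"{sid}.csv")
    return {"n_cells": int(table["cell_id"].nunique()),
            "concentrations": sorted(table["conc_uM"].unique().tolist())}


def _stage_fit_hill(ctx, sid, p):
    fit = fitting.fit_hill(ctx.get(p["input"]))
    ctx.objects[sid] = fit
    io.write_fit(fit, ctx.out / f"{sid}.json")
    return dataclasses.asdict(fit)


def _stage_ikm_sweeps(ctx, sid, p):
    boltz = fitting.BoltzmannFit(**p.get("boltzmann",
                                         {"g_max": 2.11, "v_half": -26.8, "q": 1.86}))
    ss = synth.gen_ikm_sweeps(
        synth.StepProtocol(**p.get("protocol", {})), boltz,
        tau_relax_ms=p.get("tau_relax_ms", 150.0),
        reversal_mV=p.get("reversal_mV", -91.0),
        noise=_noise(ctx, p), n_cells=p.get("n_cells", 1),
        v_half_jitter_sd=p.get("v_half_jitter_sd", 0.0))
    ctx.objects[sid] = ss
    io.write_sweepset(ss, ctx.out / f"{sid}.csv")
    return {"n_cells": p.get("n_cells", 1), "steps": list(ss.protocol.step_levels_mV)}


def _stage_fit_boltzmann(ctx, sid, p):
    ss = ctx.get(p["input"])
    gv = fitting.activation_curve(ss, v_k=p.get("v_k", -91.0))
    fit = fitting.fit_boltzmann(gv, temperature=p.get("temperature", 295.0))
    ctx.objects[sid] = fit
    io.write_fit(fit, ctx.out / f"{sid}.json")
    return dataclasses.asdict(fit)


def _stage_conductance_slope(ctx, sid, p):
    src = ctx.get(p["input"])
    if isinstance(src, synth.SweepSet):
        pts = (src.end_of_pulse().groupby("step_mV", as_index=False)["i_end_pA"]
               .mean().to_numpy(float))
    else:  # amplitude table (step_mV, amp_pA)
        pts = src.to_numpy(float)
    fit = fitting.conductance_slope(pts, window=tuple(p.get("window", (-30.0, -10.0))))
    ctx.objects[sid] = fit
    io.write_fit(fit, ctx.out / f"{sid}.json")
    return dataclasses.asdict(fit)


def _stage_single_channel(ctx, sid, p):
    spec = synth.ChannelSimSpec(**p.get("spec", {}))
    tr = synth.gen_single_channel_trace(spec, noise=_noise(ctx, p),
                                        sample_interval_ms=p.get("sample_interval_ms", 0.1))
    ctx.objects[sid] = tr
    io.write_trace(tr, ctx.out / f"{sid}.csv")
    return {"duration_ms": tr.duration_ms, "n_channels": spec.n_channels}


def _stage_npo(ctx, sid, p):
    tr = ctx.get(p["input"])
    unitary = p.get("unitary_pA")
    baseline = p.get("baseline_pA", 0.0)
    if unitary is None:
        spec = tr.meta["spec"]
        unitary = spec.unitary_amplitude_pA
        baseline = tr.meta.get("baseline_pA", 0.0)
    ideal = events.idealize_trace(tr, baseline, unitary)
    npo = events.estimate_npo(ideal)
    ctx.objects[sid] = npo
    io.write_idealization(ideal, ctx.out / f"{sid}.csv")
    io.dump_json({"NPo": npo}, ctx.out / f"{sid}.json")
    return {"NPo": npo}


def _stage_action_train(ctx, sid, p):
    tr = synth.gen_action_current_train(
        p.get("rate_hz", 1.21), p.get("duration_s", 100.0),
        noise=_noise(ctx, p), snr=p.get("snr", 10.0),
        sample_interval_ms=p.get("sample_interval_ms", 0.2))
    ctx.objects[sid] = tr
    io.write_trace(tr, ctx.out / f"{sid}.csv")
    return {"true_events": int(tr.meta["event_times_s"].size)}


def _stage_detect_events(ctx, sid, p):
    train = events.detect_action_currents(ctx.get(p["input"]), k_sd=p.get("k_sd", 6.0))
    freq = events.firing_frequency(train)
    ctx.objects[sid] = train
    io.write_event_train(train, ctx.out / f"{sid}.csv")
    return {"n_events": train.n_events, "frequency_Hz": freq}


def _stage_iv_table(ctx, sid, p):
    df = synth.gen_single_channel_iv(
        p.get("conductance_pS", 180.0), p.get("reversal_mV", 0.0),
        p.get("potentials_mV", [-60, -40, -20, 0, 20, 40, 60]),
        noise=_noise(ctx, p))
    ctx.objects[sid] = df
    io.write_dose_table(df, ctx.out / f"{sid}.csv")
    return {"n_potentials": int(df.shape[0])}


def _stage_scc(ctx, sid, p):
    df = ctx.get(p["input"])
    pS = fitting.single_channel_conductance(df.to_numpy(float),
                                            reversal=p.get("reversal_mV"))
    ctx.objects[sid] = pS
    io.dump_json({"conductance_pS": pS}, ctx.out / f"{sid}.json")
    return {"conductance_pS": pS}


def _stage_simulate(ctx, sid, p):
    mod = Modulation(**p.get("modulation", {}))
    cfg = SimConfig(dt_ms=p.get("dt_ms", 0.001),
                    duration_ms=p.get("duration_ms", 3000.0),
                    record_interval_ms=p.get("record_interval_ms", 0.01),
                    method=p.get("method", "euler"))
    tr = simulate(_model_params(p), cfg, mod)
    ctx.objects[sid] = tr
    if p.get("write_trace", True):
        io.write_sim_trace(tr, ctx.out / f"{sid}.csv")
    return {"duration_ms": cfg.duration_ms, "dt_ms": cfg.dt_ms,
            "g_M_scale": mod.g_M_scale, "g_KCa_scale": mod.g_KCa_scale}


def _stage_burst_metrics(ctx, sid, p):
    tr = ctx.get(p["input"])
    bm = burst_mod.burst_metrics(tr.v, tr.dt_record_ms,
                                 threshold_mV=p.get("threshold_mV", 0.0),
                                 gap_ms=p.get("gap_ms", 100.0),
                                 transient_ms=p.get("transient_ms", 500.0))
    ctx.objects[sid] = bm
    out = bm.to_dict()
    io.dump_json(out, ctx.out / f"{sid}.json")
    return out


def _stage_fold_change(ctx, sid, p):
    ratio = burst_mod.fold_change(ctx.get(p["a"]), ctx.get(p["b"]), p["current"],
                                  transient_ms=p.get("transient_ms", 500.0))
    ctx.objects[sid] = ratio
    return {"current": p["current"], "fold_change": ratio}


def _stage_nullcline(ctx, sid, p):
    mod = Modulation(**p.get("modulation", {}))
    ca = p.get("ca_um")
    if ca is None and "ca_from" in p:
        ca = fastslow.cycle_average_ca(ctx.get(p["ca_from"]))
    grid = np.linspace(p.get("o_min", 0.0), p.get("o_max", 1.0), p.get("n_points", 21))
    nc = fastslow.compute_nullcline(_model_params(p), o_grid=grid,
                                    ca_um=ca if ca is not None else fastslow.DEFAULT_CA_UM,
                                    modulation=mod)
    ctx.objects[sid] = nc
    io.write_curve(nc.n, nc.o, ctx.out / f"{sid}.csv",
                   meta={"params_id": nc.params_id, "ca_um": nc.ca_um})
    return {"n_points": int(nc.o.size), "ca_um": nc.ca_um}


def _stage_project(ctx, sid, p):
    lp = fastslow.project_trajectory(ctx.get(p["input"]),
                                     transient_ms=p.get("transient_ms", 1000.0))
    ctx.objects[sid] = lp
    io.write_curve(lp.n, lp.o, ctx.out / f"{sid}.csv",
                   meta={"enclosed_area": lp.enclosed_area, "degenerate": lp.degenerate})
    return {"enclosed_area": lp.enclosed_area, "degenerate": lp.degenerate}


def _stage_nullcline_shift(ctx, sid, p):
    shift = fastslow.nullcline_shift(ctx.get(p["a"]), ctx.get(p["b"]))
    ctx.objects[sid] = shift
    return {"mean_shift": shift}


_HANDLERS: Dict[str, Callable] = {
    "dose_response": _stage_dose_response,
    "fit_hill": _stage_fit_hill,
    "ikm_sweeps": _stage_ikm_sweeps,
    "fit_boltzmann": _stage_fit_boltzmann,
    "conductance_slope": _stage_conductance_slope,
    "single_channel": _stage_single_channel,
    "npo": _stage_npo,
    "action_train": _stage_action_train,
    "detect_events": _stage_detect_events,
    "iv_table": _stage_iv_table,
    "single_channel_conductance": _stage_scc,
    "simulate": _stage_simulate,
    "burst_metrics": _stage_burst_metrics,
    "fold_change": _stage_fold_change,
    "nullcline": _stage_nullcline,
    "project_trajectory": _stage_project,
    "nullcline_shift": _stage_nullcline_shift,
}


def run_scenario(scenario: Union[Scenario, dict, str, Path],
                 out_dir: Union[str, Path]) -> dict:
    """Execute a scenario and return (and write) the consolidated report."""
    if isinstance(scenario, (str, Path)):
        scenario = load_scenario(scenario)
    elif isinstance(scenario, dict):
        scenario = Scenario.model_validate(scenario)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx = _Ctx(scenario, out)

    from . import __version__
    report = {"scenario": scenario.name, "seed": scenario.seed,
              "kmburst_version": __version__, "stages": {}}
    for i, stage in enumerate(scenario.stages):
        sid = stage.id or f"stage{i:02d}_{stage.kind}"
        handler = _HANDLERS.get(stage.kind)
        if handler is None:
            raise ValueError(f"stage {sid!r}: unknown kind {stage.kind!r} "
                             f"(known: {sorted(_HANDLERS)})")
        t0 = time.perf_counter()
        try:
            entry = handler(ctx, sid, stage.params())
        except Exception as err:
            io.dump_json(report, out / "report.json")  # keep partial output
            raise RuntimeError(f"stage {sid!r} ({stage.kind}) failed: {err}") from err
        logger.info("stage=%s kind=%s seed=%s wall_s=%.2f", sid, stage.kind,
                    scenario.seed, time.perf_counter() - t0)
        report["stages"][sid] = {"kind": stage.kind, **entry}
    io.dump_json(report, out / "report.json")
    return report
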