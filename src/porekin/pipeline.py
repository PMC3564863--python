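"""End-to-end orchestration: simulate -> detect -> train -> call -> kinetics.

``run_pipeline`` executes the whole simulated experiment from one
:class:`~porekin.config.RunConfig` and writes every artifact (models,
calls, rate tables, histograms, summary report) into a run directory.  All
randomness derives from child seeds spawned from the config's master seed,
so two runs of the same config produce identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__, io
from .classify import ProtocolOptions, run_case_protocol
from .config import RunConfig
from .kinetics import (
    build_four_state_model,
    entry_conditioned_mid_stats,
    segments_for_events,
    transition_rates,
)
from .signals import (
    capture_rate,
    detect_events,
    event_histogram,
    fit_exponential_voltage,
    median_decimate,
)
from .synthetic import simulate_event_pool, simulate_trace

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("porekin")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as exc:           # noqa: BLE001 — re-raise annotated
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@_stage("simulate+detect")
def _capture_stage(cfg: RunConfig, syn, rng, outdir: Path) -> dict:
    """Per-voltage trace simulation, detection and capture statistics."""
    rows = []
    for v in cfg.voltages_mV:
        trace, truth = simulate_trace(syn, cfg.trace_duration_s, v,
                                      class_label=cfg.trace_class, rng=rng)
        dec = median_decimate(trace)
        i0 = trace.metadata["open_pore_current_pA"]
        events = detect_events(dec, i0, enter_frac=cfg.enter_frac,
                               exit_frac=cfg.exit_frac, voltage_mV=v,
                               dt_s=cfg.dt_s)
        blocked = sum(e.lifetime_s for e in events)
        open_time = max(trace.duration_s - blocked, 1e-9)
        rate, se, flagged = capture_rate(events, open_time, n_boot=cfg.n_boot, rng=rng)
        rows.append({"voltage_mV": v, "n_events": len(events),
                     "n_true_events": len(truth.boundaries),
                     "open_pore_time_s": open_time,
                     "rate_hz": rate, "rate_se_hz": se, "zero_flag": flagged})
        log.info("  V=%+.0f mV: %d events, rate %.3f /s", v, len(events), rate)
    usable = [r for r in rows if r["rate_hz"] > 0]
    fit = None
    if len({r["voltage_mV"] for r in usable}) >= 2:
        f = fit_exponential_voltage([r["voltage_mV"] for r in usable],
                                    [r["rate_hz"] for r in usable])
        fit = dataclasses.asdict(f)
    out = {"per_voltage": rows, "exponential_fit": fit}
    io.write_json(out, outdir / "capture_stats.json")
    return out


@_stage("pools")
def _pool_stage(cfg: RunConfig, syn, rng, outdir: Path):
    pools = {}
    for cls in ("wt", "mut"):
        pools[cls] = simulate_event_pool(syn, cls, cfg.pool_size,
                                         cfg.pool_voltage_mV, rng)
        io.write_events(pools[cls], outdir / f"events_{cls}.tsv")
    edges, density = event_histogram(pools["wt"], n_bins=120, value_range=(-0.1, 1.1))
    np.savetxt(outdir / "histogram_wt.tsv",
               np.column_stack([0.5 * (edges[:-1] + edges[1:]), density]),
               delimiter="\t", header="I_over_I0\tdensity", comments="")
    return pools


@_stage("protocol")
def _protocol_stage(cfg: RunConfig, pools, rng, outdir: Path):
    n = cfg.n_per_class if cfg.case == 1 else cfg.n_per_class_case2
    opts = ProtocolOptions(n_per_class=n, K=cfg.K, max_iter=cfg.max_iter, tol=cfg.tol)
    result, m_wt, m_mut = run_case_protocol(pools["wt"], pools["mut"],
                                            cfg.case, opts, rng)
    m_wt.save(outdir / "model_wt.json", meta={"trained_on": f"case {cfg.case} remainder"})
    m_mut.save(outdir / "model_mut.json", meta={"trained_on": f"case {cfg.case} remainder"})
    with open(outdir / "calls.tsv", "w") as fh:
        fh.write("event_id\tloglik_wt\tloglik_mut\tcall\ttruth\n")
        for r in result.records:
            fh.write(f"{r.event_id}\t{r.loglik_wt:.6f}\t{r.loglik_mut:.6f}"
                     f"\t{r.call}\t{r.true_label}\n")
    io.write_json(result.summary(), outdir / "calls_summary.json")
    return result, m_wt, m_mut


@_stage("kinetics")
def _kinetics_stage(cfg: RunConfig, pools, model, rng, outdir: Path):
    events = pools["wt"][:cfg.kinetics_events]
    segs = segments_for_events(events, model)
    table = transition_rates(segs, K=model.K, n_boot=cfg.n_boot, rng=rng,
                             voltage_mV=cfg.pool_voltage_mV)
    io.write_rate_table(table, outdir / "rates.tsv")
    cond = entry_conditioned_mid_stats(segs, mid_state=1, high_state=2,
                                       low_state=0, n_boot=cfg.n_boot, rng=rng)
    cond_out = {
        name: {
            "n_segments": c.n_segments,
            "T_s": c.T_s,
            "rate_hz": {str(k): v for k, v in c.rate_hz.items()},
            "se_hz": {str(k): v for k, v in c.se_hz.items()},
            "defined": c.defined,
        }
        for name, c in cond.items()
    }
    io.write_json(cond_out, outdir / "mid_state_conditioned.json")
    four = None
    try:
        fsm = build_four_state_model(segs, model, mid_state=1)
        four = {"state_names": list(fsm.state_names), "A": fsm.A,
                "q": fsm.q, "b": fsm.b, "provenance": fsm.provenance}
        io.write_json({"label": "four-state", "K": 4, **four},
                      outdir / "model_four_state.json")
    except ValueError as exc:
        log.warning("four-state split not possible: %s", exc)
    return {"rate_table": str(outdir / "rates.tsv"),
            "conditioned": cond_out, "four_state": four}


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run the full simulated experiment; returns (and writes) the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(message)s")

    rng_capture, rng_pool, rng_protocol, rng_kin = cfg.child_seeds(4)

    capture = _capture_stage(cfg, cfg.synthetic_config(), rng_capture, outdir)
    pools = _pool_stage(cfg, cfg.synthetic_config(), rng_pool, outdir)
    result, m_wt, m_mut = _protocol_stage(cfg, pools, rng_protocol, outdir)
    kin = _kinetics_stage(cfg, pools, m_wt, rng_kin, outdir)

    summary = {
        "porekin_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "capture": capture,
        "protocol": result.summary(),
        "kinetics": {"conditioned": kin["conditioned"],
                     "four_state_available": kin["four_state"] is not None},
    }
    io.write_json(summary, outdir / "summary.json")
    return json.loads((outdir / "summary.json").read_text())
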