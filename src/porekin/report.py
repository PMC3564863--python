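"""Human-readable report rendering for a completed pipeline run.

Regenerates tables and figures (event histogram, model parameter tables,
predictive-value table, rate-vs-voltage plot) from the artifacts already in
a run directory, without recomputation.  Missing artifacts are listed and
the report is still produced for whatever exists.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["render_report"]


def _fmt_model(d: dict) -> str:
    lines = [f"label: {d.get('label', '')}  (K={d.get('K')})",
             "state   q        b        pi",]
    for k in range(d["K"]):
        lines.append(f"{k:>5}   {d['q'][k]:<7.4f}  {d['b'][k]:<7.4f}  {d['pi'][k]:<7.4f}")
    lines.append("A = " + json.dumps([[round(x, 4) for x in row] for row in d["A"]]))
    return "\n".join(lines)


def render_report(run_dir: str | Path) -> Path:
    """Write ``report.md`` (plus PNG figures) summarizing a run directory."""
    run_dir = Path(run_dir)
    missing: list[str] = []
    parts: list[str] = ["# porekin run report\n"]

    summary_p = run_dir / "summary.json"
    if summary_p.exists():
        summary = json.loads(summary_p.read_text())
        parts.append(f"config hash: `{summary['config_hash']}`  "
                     f"seed: {summary['seed']}  version: {summary['porekin_version']}\n")
    else:
        summary = None
        missing.append("summary.json")

    # capture rate vs voltage
    cap_p = run_dir / "capture_stats.json"
    if cap_p.exists():
        cap = json.loads(cap_p.read_text())
        rows = [r for r in cap["per_voltage"] if r["rate_hz"] > 0]
        skipped = [r["voltage_mV"] for r in cap["per_voltage"] if r["rate_hz"] <= 0]
        if rows:
            v = [r["voltage_mV"] for r in rows]
            r_ = [r["rate_hz"] for r in rows]
            e = [r["rate_se_hz"] for r in rows]
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.errorbar(v, r_, yerr=e, fmt="o")
            ax.set_yscale("log")
            ax.set_xlabel("voltage (mV)")
            ax.set_ylabel("capture rate (s$^{-1}$)")
            fig.tight_layout()
            fig.savefig(run_dir / "capture_rate.png", dpi=120)
            plt.close(fig)
            parts.append("## Capture rate vs voltage\n\n"
                         "![capture rate](capture_rate.png)\n")
            if cap.get("exponential_fit"):
                f = cap["exponential_fit"]
                parts.append(f"exponential fit: R0 = {f['prefactor']:.4g} /s, "
                             f"V_scale = {f['voltage_scale_mV']:.1f} mV "
                             f"(R^2 = {f['r_squared']:.3f})\n")
        if skipped:
            parts.append(f"voltages omitted (zero events): {skipped}\n")
    else:
        missing.append("capture_stats.json")

    # event histogram
    hist_p = run_dir / "histogram_wt.tsv"
    if hist_p.exists():
        h = np.loadtxt(hist_p, skiprows=1)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(h[:, 0], h[:, 1])
        ax.set_xlabel("I/I$_0$")
        ax.set_ylabel("density")
        fig.tight_layout()
        fig.savefig(run_dir / "histogram_wt.png", dpi=120)
        plt.close(fig)
        parts.append("## All-point event histogram (wild-type pool)\n\n"
                     "![histogram](histogram_wt.png)\n")
    else:
        missing.append("histogram_wt.tsv")

    # models
    for name in ("model_wt.json", "model_mut.json"):
        p = run_dir / name
        if p.exists():
            parts.append(f"## {name}\n\n```\n"
                         f"{_fmt_model(json.loads(p.read_text()))}\n```\n")
        else:
            missing.append(name)

    # predictive values (undefined flags reported verbatim, never 0-filled)
    calls_p = run_dir / "calls_summary.json"
    if calls_p.exists():
        s = json.loads(calls_p.read_text())
        def _fmt(x):
            return "undefined" if x is None else f"{x:.3f}"
        parts.append("## Predictive values\n\n"
                     "| | value |\n|---|---|\n"
                     f"| mix size | {s['mix_size']} |\n"
                     f"| wild-type predictive value | {_fmt(s['ppv_wt'])} |\n"
                     f"| mutant predictive value | {_fmt(s['ppv_mut'])} |\n")
    else:
        missing.append("calls_summary.json")

    if missing:
        parts.append("## Missing artifacts\n\n" +
                     "\n".join(f"- {m}" for m in missing) + "\n")
    out = run_dir / "report.md"
    out.write_text("\n".join(parts))
    return out
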