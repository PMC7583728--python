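"""Delimited-text and JSON serialization of analysis artifacts.

Event tables are tab-separated with one row per transition; analysis results
are saved as a directory of plain-text artifacts (corrected trace, event
table, baseline report, gating summary, audit log) so they can be inspected,
versioned, and edited headlessly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import BaselineModel
from .fitting import ErfFit, TransitionEvent
from .gating import GatingSummary
from .pipeline import AnalysisResult, PipelineConfig
from .simulate import GatingEvent, GroundTruth, SimulationConfig
from .trace import Trace, read_trace, write_trace

__all__ = [
    "events_to_dataframe",
    "write_event_table",
    "read_event_table",
    "write_ground_truth",
    "save_result",
    "load_result",
    "write_simulation_config",
    "read_simulation_config",
]

EVENT_COLUMNS = [
    "trace_id", "t_trans_s", "direction", "a_trans_pA", "conductance_pS",
    "tc_trans_ms", "A_pA", "B_ms", "C_pA", "residual_rms_pA", "provenance",
    "state_class", "event_id",
]


def events_to_dataframe(events) -> pd.DataFrame:
    rows = []
    for ev in events:
        fit = ev.fit
        rows.append({
            "trace_id": ev.trace_id,
            "t_trans_s": ev.t_trans,
            "direction": ev.direction,
            "a_trans_pA": ev.a_trans_pa,
            "conductance_pS": ev.conductance_ps,
            "tc_trans_ms": ev.tc_trans_ms,
            "A_pA": fit.A if fit else math.nan,
            "B_ms": fit.B * 1e3 if fit and math.isfinite(fit.B) else math.nan,
            "C_pA": fit.C if fit else math.nan,
            "residual_rms_pA": fit.residual_rms if fit else math.nan,
            "provenance": ev.provenance,
            "state_class": ev.state_class,
            "event_id": ev.event_id,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_event_table(events, path: str | Path) -> None:
    events_to_dataframe(events).to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path) -> list[TransitionEvent]:
    df = pd.read_csv(path, sep="\t")
    events = []
    for _, row in df.iterrows():
        fit = None
        if math.isfinite(row["A_pA"]):
            b_s = row["B_ms"] * 1e-3 if math.isfinite(row["B_ms"]) else math.nan
            fit = ErfFit(A=row["A_pA"], B=b_s, C=row["C_pA"],
                         t_center=row["t_trans_s"], window=(math.nan, math.nan),
                         residual_rms=row["residual_rms_pA"],
                         converged=math.isfinite(row["B_ms"]))
        events.append(TransitionEvent(
            t_trans=row["t_trans_s"], direction=row["direction"],
            a_trans_pa=row["a_trans_pA"], conductance_ps=row["conductance_pS"],
            tc_trans_ms=row["tc_trans_ms"], fit=fit,
            provenance=row["provenance"], state_class=row["state_class"],
            trace_id=str(row["trace_id"]), event_id=str(row["event_id"])))
    return events


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = [{
        "time_s": ev.time_s, "direction": ev.direction,
        "amplitude_pA": ev.amplitude_pa, "tc_ms": ev.tc_ms,
        "state": ev.state, "channel": ev.channel,
    } for ev in truth.events]
    pd.DataFrame(rows, columns=["time_s", "direction", "amplitude_pA",
                                "tc_ms", "state", "channel"]
                 ).to_csv(path, sep="\t", index=False)


def write_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    payload = dataclasses.asdict(config)
    payload["state_levels"] = [list(s) for s in config.state_levels]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_simulation_config(path: str | Path) -> SimulationConfig:
    payload = json.loads(Path(path).read_text())
    payload["state_levels"] = tuple(tuple(s) for s in payload["state_levels"])
    return SimulationConfig(**payload)


def _summary_dict(summary: GatingSummary) -> dict:
    return dataclasses.asdict(summary)


def write_cohort_summary(results, path: str | Path) -> None:
    """Cohort-level delimited table: one row of gating metrics per trace."""
    rows = []
    for res in results:
        row = {"trace_id": res.trace_id}
        row.update(_summary_dict(res.summary))
        row["baseline_family"] = res.baseline.family if res.baseline else ""
        row["converged"] = res.converged
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_component_table(components, path: str | Path) -> None:
    """Gaussian-component table (mean, SD, amplitude, AUC) as TSV."""
    rows = [{"mean_pS": c.mean, "sd_pS": c.sd, "amplitude": c.amplitude,
             "auc": c.auc, "flag": c.flag} for c in components]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_tc_report(fit, path: str | Path) -> None:
    """Exponential-fit report (components, taus, weights, LRT score) as JSON."""
    payload = {
        "n_components": fit.n_components,
        "taus_ms": list(fit.taus),
        "weights": list(fit.weights),
        "model_score": fit.model_score,
        "flag": fit.flag,
        "alternatives": {str(k): {"taus_ms": list(t), "weights": list(w)}
                         for k, (t, w, _) in fit.alternatives.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def save_result(result: AnalysisResult, out_dir: str | Path) -> Path:
    """Save an analysis result as a directory of text artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trace(result.raw_trace, out / "raw_trace.txt")
    write_trace(result.corrected_trace, out / "corrected_trace.txt")
    write_event_table(result.events, out / "events.tsv")
    report = {
        "trace_id": result.trace_id,
        "converged": result.converged,
        "summary": _summary_dict(result.summary),
        "audit_log": result.audit_log,
        "baseline": None,
    }
    if result.baseline is not None:
        report["baseline"] = {
            "family": result.baseline.family,
            "params": result.baseline.params,
            "fit_rss": result.baseline.fit_rss,
            "aic": result.baseline.aic,
            "alternatives": {
                name: {"params": p, "rss": rss, "aic": aic}
                for name, (p, rss, aic) in result.baseline.alternatives.items()
            },
        }
    (out / "result.json").write_text(json.dumps(report, indent=2))
    return out


def load_result(result_dir: str | Path,
                config: PipelineConfig | None = None) -> AnalysisResult:
    """Load a saved result directory back into an :class:`AnalysisResult`."""
    out = Path(result_dir)
    report = json.loads((out / "result.json").read_text())
    baseline = None
    if report["baseline"] is not None:
        b = report["baseline"]
        baseline = BaselineModel(
            family=b["family"], params=b["params"], fit_rss=b["fit_rss"],
            aic=b["aic"],
            alternatives={name: (alt["params"], alt["rss"], alt["aic"])
                          for name, alt in b["alternatives"].items()})
    summary = GatingSummary(**report["summary"])
    return AnalysisResult(
        trace_id=report["trace_id"],
        raw_trace=read_trace(out / "raw_trace.txt"),
        corrected_trace=read_trace(out / "corrected_trace.txt"),
        events=read_event_table(out / "events.tsv"),
        baseline=baseline,
        summary=summary,
        audit_log=report["audit_log"],
        converged=report["converged"],
        config=config or PipelineConfig(),
    )
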