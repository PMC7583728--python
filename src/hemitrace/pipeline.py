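"""Full per-trace analysis and the headless manual-edit API.

``analyze_trace`` runs the complete chain: median filter -> derivative
threshold candidate detection -> TVD denoising -> time refinement -> erf
transition fits -> idealized-trace construction -> baseline fit -> iterative
reanalysis -> gating metrics. The result carries an audit log; the
``add_event`` / ``remove_event`` operations are the headless equivalent of
interactive event correction and keep all downstream quantities consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .baseline import (BaselineModel, build_idealized, correct_and_reanalyze,
                       fit_baseline)
from .detection import (DEFAULT_NOISE_SD_PS, CandidateEvent, DetectionConfig,
                        detect_candidates, refine_event_time)
from .distributions import GaussianComponent
from .filtering import FilterConfig, median_filter, tvd_denoise
from .fitting import (JOINT_FIT_GAP_SAMPLES, TransitionEvent, fit_transition,
                      fit_transition_pair)
from .gating import GatingSummary, compute_npo, count_transitions
from .trace import Trace

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_trace",
           "detect_and_fit", "add_event", "remove_event", "replay_audit"]

log = logging.getLogger(__name__)

#: Reference conductance states used for per-event classification and the
#: default open level: fully open 217 +/- 66 pS, substate 80 +/- 28 pS.
DEFAULT_STATE_COMPONENTS = (
    GaussianComponent(mean=80.0, sd=28.0, amplitude=1.0),
    GaussianComponent(mean=217.0, sd=66.0, amplitude=1.0),
)


@dataclass
class PipelineConfig:
    """End-to-end analysis settings (all stages)."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    fit_halfwindow: float = 0.15  # s, erf fitting half-window
    baseline_correction: bool = True
    max_cycles: int = 5
    state_components: tuple = DEFAULT_STATE_COMPONENTS
    open_level_ps: float | None = None  # None: mean of the main component
    npo_threshold_fraction: float = 0.5
    #: manual additions below this conductance are refused as noise
    manual_min_conductance_ps: float = 20.0
    #: threshold of the final detection pass on the fully corrected trace.
    #: The 60 pS default of ``detection.threshold_ps`` serves the initial
    #: passes that isolate the baseline; once the drift is removed, smaller
    #: transitions (down to the background-noise SD) are resolvable and
    #: belong in the finalized analysis. None disables the extra pass.
    final_threshold_ps: float | None = DEFAULT_NOISE_SD_PS

    def open_level_pa(self, vm: float) -> float:
        ps = self.open_level_ps
        if ps is None:
            ps = max(c.mean for c in self.state_components)
        return ps * abs(vm) / 1000.0


@dataclass
class AnalysisResult:
    """Everything produced by one trace analysis."""

    trace_id: str
    raw_trace: Trace
    corrected_trace: Trace
    events: list
    baseline: BaselineModel | None
    summary: GatingSummary
    audit_log: list = field(default_factory=list)
    converged: bool = True
    config: PipelineConfig = field(default_factory=PipelineConfig)


def _make_event(trace: Trace, cand_direction: str, fit, config: PipelineConfig,
                provenance: str = "auto") -> TransitionEvent:
    vm = trace.vm
    vsign = 1.0 if vm >= 0 else -1.0
    a_signed = fit.a_trans_pa * vsign
    trace_id = str(trace.metadata.get("trace_id", ""))
    idx = trace.time_to_index(fit.t_center)
    return TransitionEvent(
        t_trans=fit.t_center,
        direction=cand_direction,
        a_trans_pa=a_signed,
        conductance_ps=1000.0 * a_signed / vm,
        tc_trans_ms=fit.tc_trans_ms,
        fit=fit,
        provenance=provenance,
        trace_id=trace_id,
        event_id=f"{trace_id}:{idx}:{cand_direction[0]}",
    )


def detect_and_fit(trace: Trace, config: PipelineConfig | None = None
                   ) -> list[TransitionEvent]:
    """One detection pass: median filter, thresholding, TVD refinement,
    erf fits. Returns events sorted by time."""
    config = config or PipelineConfig()
    m = median_filter(trace, config.filter.t_mf)
    candidates = detect_candidates(m, config.detection)
    if not candidates:
        return []
    tvd = tvd_denoise(trace, config.filter.tvd_lambda,
                      config.filter.tvd_iterations)
    refined: list[tuple[float, CandidateEvent]] = []
    for cand in candidates:
        t = refine_event_time(tvd, cand, config.detection.refine_halfwindow)
        refined.append((t, cand))
    refined.sort(key=lambda r: r[0])

    # refinement can funnel two candidates onto one edge: dedupe by sample
    dedup: list[tuple[float, CandidateEvent]] = []
    for t, cand in refined:
        if dedup and cand.direction == dedup[-1][1].direction and \
                abs(t - dedup[-1][0]) * trace.sampling_rate <= 2:
            if cand.approx_amplitude > dedup[-1][1].approx_amplitude:
                dedup[-1] = (t, cand)
            continue
        dedup.append((t, cand))

    times = [t for t, _ in dedup]
    events: list[TransitionEvent] = []
    i = 0
    gap_s = JOINT_FIT_GAP_SAMPLES / trace.sampling_rate
    while i < len(dedup):
        t, cand = dedup[i]
        neighbors = times[:i] + times[i + 1:]
        if i + 1 < len(dedup) and times[i + 1] - t < gap_s:
            t2, cand2 = dedup[i + 1]
            try:
                f1, f2 = fit_transition_pair(trace, t, t2,
                                             config.fit_halfwindow)
                events.append(_make_event(trace, cand.direction, f1, config))
                events.append(_make_event(trace, cand2.direction, f2, config))
                i += 2
                continue
            except (RuntimeError, ValueError):
                log.warning("joint fit failed at t=%.3f s; fitting separately", t)
        fit = fit_transition(trace, t, config.fit_halfwindow, neighbors)
        events.append(_make_event(trace, cand.direction, fit, config))
        i += 1
    events.sort(key=lambda ev: ev.t_trans)
    return events


def _summarize(corrected: Trace, events, config: PipelineConfig) -> GatingSummary:
    summary = compute_npo(corrected, config.open_level_pa(corrected.vm),
                          config.npo_threshold_fraction)
    counts = count_transitions(events, config.state_components,
                               recording_time_s=corrected.duration)
    summary.n_transitions_total = counts["n_transitions_total"]
    summary.n_main = counts["n_main"]
    summary.n_substate = counts["n_substate"]
    summary.n_unclassified = counts["n_unclassified"]
    summary.transitions_per_30s = counts["transitions_per_30s"]
    return summary


def analyze_trace(trace: Trace, config: PipelineConfig | None = None
                  ) -> AnalysisResult:
    """Run the full semi-automated analysis on one trace.

    Deterministic: identical inputs and configuration produce bit-identical
    event tables. An empty event list is a valid outcome (flat traces).
    """
    import time

    config = config or PipelineConfig()
    t0 = time.perf_counter()
    events = detect_and_fit(trace, config)
    log.info("detection+fitting: %d events in %.2f s", len(events),
             time.perf_counter() - t0)
    baseline = None
    corrected = trace
    converged = True
    if config.baseline_correction:
        t0 = time.perf_counter()
        rean = correct_and_reanalyze(trace, config, events, config.max_cycles)
        corrected, events, baseline = rean.corrected, rean.events, rean.baseline
        converged = rean.converged
        log.info("baseline reanalysis: %d cycle(s), family=%s in %.2f s",
                 rean.n_cycles, baseline.family if baseline else None,
                 time.perf_counter() - t0)
    if (config.final_threshold_ps is not None
            and config.final_threshold_ps < config.detection.threshold_ps):
        # finalized analysis: with the drift removed, re-detect at the
        # lower threshold so sub-threshold transitions enter the result
        final_cfg = replace(
            config,
            detection=replace(config.detection,
                              threshold_ps=config.final_threshold_ps))
        events = detect_and_fit(corrected, final_cfg)
    result = AnalysisResult(
        trace_id=str(trace.metadata.get("trace_id", "")),
        raw_trace=trace,
        corrected_trace=corrected,
        events=events,
        baseline=baseline,
        summary=GatingSummary(),
        converged=converged,
        config=config,
    )
    # final consistency pass: baseline, corrected trace and summary become a
    # pure function of (raw trace, event list, config) — the same mapping the
    # manual-edit operations use, so edits and their inverses round-trip
    return _recompute(result)


def _recompute(result: AnalysisResult) -> AnalysisResult:
    """Rebuild idealized trace, baseline, corrected trace and summary from
    the current event list (event fits are kept as-is, so an add followed by
    a remove restores the previous result exactly)."""
    trace = result.raw_trace
    config = result.config
    baseline = result.baseline
    corrected = result.corrected_trace
    if config.baseline_correction:
        ideal = build_idealized(trace, result.events)
        baseline = fit_baseline(trace.with_samples(trace.samples - ideal.samples))
        corrected = trace.with_samples(trace.samples - baseline.evaluate(trace))
    summary = _summarize(corrected, result.events, config)
    return replace(result, corrected_trace=corrected, baseline=baseline,
                   summary=summary)


def add_event(result: AnalysisResult, approx_time: float, direction: str,
              search_halfwidth: int = 500) -> AnalysisResult:
    """Insert a missed transition near ``approx_time``.

    The steepest sign-consistent derivative of the TVD-denoised corrected
    trace within ``search_halfwidth`` samples of ``approx_time`` is taken as
    the transition time; the event is erf-fitted and inserted with
    provenance "manual", and all downstream quantities are recomputed. If
    the local level change is below the manual-addition floor
    (``manual_min_conductance_ps``) the region is considered flat and the
    addition refused.
    """
    if direction not in ("opening", "closing"):
        raise ValueError("direction must be 'opening' or 'closing'")
    trace = result.corrected_trace
    config = result.config
    n = len(trace)
    center = trace.time_to_index(approx_time, clip=False)
    i_lo = max(0, center - search_halfwidth)
    i_hi = min(n - 1, center + search_halfwidth)
    if i_hi - i_lo < 2:
        raise ValueError("search window outside the trace")

    tvd = tvd_denoise(trace, config.filter.tvd_lambda,
                      config.filter.tvd_iterations)
    d = np.diff(tvd.samples[i_lo:i_hi + 1])
    vsign = 1.0 if trace.vm >= 0 else -1.0
    want = 1.0 if direction == "opening" else -1.0
    signed = d * vsign * want
    if not (signed > 0).any():
        raise ValueError("no sign-consistent derivative in the search window; "
                         "nothing to add")
    k = i_lo + int(np.argmax(signed))
    # level change across the edge, measured a few samples out on each side
    pad = 8
    j0, j1 = max(0, k - pad), min(n - 1, k + 1 + pad)
    level_change = (tvd.samples[j1] - tvd.samples[j0]) * vsign * want
    floor_pa = config.manual_min_conductance_ps * abs(trace.vm) / 1000.0
    if level_change < floor_pa:
        raise ValueError(
            f"local level change ({level_change:.3g} pA) below the manual "
            f"addition floor ({floor_pa:.3g} pA); region looks flat")

    t_edge = trace.index_to_time(k) + 0.5 / trace.sampling_rate
    neighbors = [ev.t_trans for ev in result.events]
    fit = fit_transition(trace, t_edge, config.fit_halfwindow, neighbors)
    event = _make_event(trace, direction, fit, config, provenance="manual")
    new_events = sorted(result.events + [event], key=lambda ev: ev.t_trans)
    out = replace(result, events=new_events,
                  audit_log=result.audit_log + [
                      {"op": "add", "approx_time": approx_time,
                       "direction": direction,
                       "search_halfwidth": search_halfwidth,
                       "event_id": event.event_id}])
    return _recompute(out)


def remove_event(result: AnalysisResult, event_id: str) -> AnalysisResult:
    """Remove an event by id and recompute downstream quantities."""
    matches = [ev for ev in result.events if ev.event_id == event_id]
    if not matches:
        raise KeyError(f"no event with id {event_id!r}")
    new_events = [ev for ev in result.events if ev.event_id != event_id]
    out = replace(result, events=new_events,
                  audit_log=result.audit_log + [
                      {"op": "remove", "event_id": event_id}])
    return _recompute(out)


def replay_audit(trace: Trace, config: PipelineConfig,
                 audit_log: list) -> AnalysisResult:
    """Re-run an analysis and re-apply a recorded edit sequence."""
    result = analyze_trace(trace, config)
    for entry in audit_log:
        if entry["op"] == "add":
            result = add_event(result, entry["approx_time"], entry["direction"],
                               entry.get("search_halfwidth", 500))
        elif entry["op"] == "remove":
            result = remove_event(result, entry["event_id"])
        else:
            raise ValueError(f"unknown audit entry {entry!r}")
    return result
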