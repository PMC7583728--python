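"""Transition candidate detection and time refinement.

Candidates are found on the median-filtered trace: the level change at the
transition scale is measured by a lagged difference
``D[i] = m[i + L] - m[i - L]`` whose span ``2L`` equals the median window,
and a candidate is raised wherever ``|D|`` exceeds the conductance threshold
(default 60 pS, i.e. twice the 30 pS background-noise SD, expressed in pA
via the step potential). The lagged difference measures the full amplitude
of a step while slow drift only contributes ``slope x 2L``, far below
threshold, so drifting baselines do not fire the detector.

The median filter distorts transition times, so each candidate time is then
refined on the TVD-denoised trace: the maximum-magnitude, sign-consistent
first difference within +/-300 ms of the approximate time gives the exact
transition time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trace import Trace

__all__ = [
    "DetectionConfig",
    "CandidateEvent",
    "detect_candidates",
    "refine_event_time",
    "DEFAULT_NOISE_SD_PS",
]

log = logging.getLogger(__name__)

#: Background-noise SD the default threshold is derived from (pS-equivalent).
DEFAULT_NOISE_SD_PS = 30.0


@dataclass
class DetectionConfig:
    """Detection thresholds and windows.

    ``threshold_ps`` defaults to twice the background-noise SD
    (2 x 30 pS = 60 pS). ``lag_s`` is the half-span of the lagged
    difference (half the median window). ``min_separation`` merges
    same-direction candidates produced by a single edge, keeping the larger.
    """

    threshold_ps: float = 2.0 * DEFAULT_NOISE_SD_PS
    refine_halfwindow: float = 0.3  # s
    min_separation: float = 0.15  # s (half the median window)
    lag_s: float = 0.15  # s

    def __post_init__(self) -> None:
        if not self.threshold_ps > 0:
            raise ValueError("threshold_ps must be > 0")
        if not self.refine_halfwindow > 0:
            raise ValueError("refine_halfwindow must be > 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if not self.lag_s > 0:
            raise ValueError("lag_s must be > 0")


@dataclass
class CandidateEvent:
    """Approximate transition location from the median-filtered trace."""

    t_mf_time: float  # s
    direction: str  # "opening" | "closing"
    approx_amplitude: float  # pA, > 0


def detect_candidates(median_trace: Trace,
                      config: DetectionConfig | None = None) -> list[CandidateEvent]:
    """Threshold the lagged derivative of the median-filtered trace.

    Returns one candidate per contiguous super-threshold region of
    constant-sign lagged difference, placed at the steepest point; candidates
    of equal direction closer than ``min_separation`` are merged keeping the
    larger amplitude.
    """
    config = config or DetectionConfig()
    if median_trace.vm == 0:
        raise ValueError("vm must be nonzero: the conductance threshold is "
                         "undefined at 0 mV")
    if len(median_trace) < 2:
        raise ValueError("trace must have at least 2 samples")
    m = median_trace.samples
    fs = median_trace.sampling_rate
    lag = max(1, int(round(config.lag_s * fs)))
    if 2 * lag >= m.size:
        lag = max(1, (m.size - 1) // 2)
    thr_pa = config.threshold_ps * abs(median_trace.vm) / 1000.0
    vsign = 1.0 if median_trace.vm > 0 else -1.0

    # D[i] = m[i + lag] - m[i - lag], valid for i in [lag, n - lag)
    d = m[2 * lag:] - m[:-2 * lag]
    idx0 = lag  # trace index of d[0]
    over = np.abs(d) > thr_pa
    if not over.any():
        return []

    sign = np.sign(d)
    # split super-threshold samples into runs of constant sign
    breaks = np.flatnonzero(np.diff(over.astype(int) * sign) != 0) + 1
    candidates: list[CandidateEvent] = []
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, d.size]):
        seg = d[lo:hi]
        if seg.size == 0 or not over[lo]:
            continue
        # steepest point of the region; a clean step yields a flat plateau
        # of maximal differences, so take the plateau midpoint
        amp = float(np.max(np.abs(seg)))
        plateau = np.flatnonzero(np.abs(seg) >= amp * (1.0 - 1e-9))
        k = lo + int(plateau[plateau.size // 2])
        direction = "opening" if sign[k] * vsign > 0 else "closing"
        candidates.append(CandidateEvent(
            t_mf_time=median_trace.index_to_time(k + idx0),
            direction=direction,
            approx_amplitude=float(amp),
        ))

    # merge same-direction duplicates from one edge
    candidates.sort(key=lambda c: c.t_mf_time)
    merged: list[CandidateEvent] = []
    for c in candidates:
        if (merged and c.direction == merged[-1].direction
                and c.t_mf_time - merged[-1].t_mf_time < config.min_separation):
            if c.approx_amplitude > merged[-1].approx_amplitude:
                merged[-1] = c
        else:
            merged.append(c)
    return merged


def refine_event_time(tvd_trace: Trace, candidate: CandidateEvent,
                      halfwindow: float = 0.3) -> float:
    """Exact transition time: steepest sign-consistent TVD derivative.

    Searches ``[t_mf - halfwindow, t_mf + halfwindow]`` for the
    maximum-magnitude first difference whose sign matches the candidate
    direction; returns its midpoint time. If no sign-consistent difference
    exists, the candidate is unrefinable: the approximate time is kept and a
    warning logged.
    """
    if not halfwindow > 0:
        raise ValueError("halfwindow must be > 0")
    fs = tvd_trace.sampling_rate
    n = len(tvd_trace)
    i_lo = max(0, tvd_trace.time_to_index(candidate.t_mf_time - halfwindow))
    i_hi = min(n - 1, tvd_trace.time_to_index(candidate.t_mf_time + halfwindow))
    if i_hi <= i_lo:
        raise ValueError("refinement window does not intersect the trace")
    d = np.diff(tvd_trace.samples[i_lo:i_hi + 1])
    vsign = 1.0 if tvd_trace.vm >= 0 else -1.0
    want = 1.0 if candidate.direction == "opening" else -1.0
    signed = d * vsign * want
    if not (signed > 0).any():
        log.warning("no sign-consistent TVD derivative near t=%.3f s; "
                    "keeping approximate time", candidate.t_mf_time)
        return candidate.t_mf_time
    k = int(np.argmax(signed))
    # the steepest difference lies between samples k and k+1
    return tvd_trace.index_to_time(i_lo + k) + 0.5 / fs
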