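"""Error-function fitting of individual transitions.

Each refined transition is fitted to

    f(t; A, B, C) = A * erf((t - t_c) / B) + C

over a +/-150 ms window (the window size equals the 300 ms maximum
transition time). The transition amplitude is ``a_trans = 2|A|`` and the
characteristic time constant ``tc_trans = B``. The center ``t_c`` is also
fitted, tightly bounded around the refined time, because freezing it at the
sample grid would bias ``B`` for fast edges. If another transition falls
inside the window, the window is shrunk to the midpoint toward that
neighbor; transitions that end up closer than 20 samples are fitted jointly
as a sum of two erf terms so their amplitudes do not cross-contaminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf

from .trace import Trace

__all__ = [
    "ErfFit",
    "TransitionEvent",
    "fit_transition",
    "fit_transition_pair",
    "classify_state",
    "MAX_TC_S",
]

log = logging.getLogger(__name__)

#: Upper bound on the fitted time constant, seconds (maximum transition time).
MAX_TC_S = 0.3

#: Events closer than this many samples are fitted jointly.
JOINT_FIT_GAP_SAMPLES = 20


@dataclass
class ErfFit:
    """Fitted parameters of one erf-shaped transition edge."""

    A: float  # half-amplitude, pA (signed)
    B: float  # time constant, s (> 0)
    C: float  # local offset, pA
    t_center: float  # s
    window: tuple  # (start s, end s)
    residual_rms: float  # pA
    converged: bool = True

    @property
    def a_trans_pa(self) -> float:
        """Transition amplitude 2|A| in pA."""
        return 2.0 * abs(self.A)

    @property
    def tc_trans_ms(self) -> float:
        """Transition time constant |B| in ms (NaN when not identified)."""
        return abs(self.B) * 1e3 if np.isfinite(self.B) else float("nan")


@dataclass
class TransitionEvent:
    """One opening or closing transition with its fitted parameters."""

    t_trans: float  # s
    direction: str  # "opening" | "closing"
    a_trans_pa: float  # signed like vm (positive at positive potentials)
    conductance_ps: float  # a_trans / vm, > 0
    tc_trans_ms: float  # NaN when the fit did not converge
    fit: ErfFit | None = None
    provenance: str = "auto"  # "auto" | "manual"
    state_class: str = "pending"  # "main" | "substate" | "unclassified" | "pending"
    trace_id: str = ""
    event_id: str = ""
    extras: dict = field(default_factory=dict)


def _erf_model(t, a, b, c, tc):
    return a * erf((t - tc) / b) + c


def _shrink_window(t_trans: float, lo: float, hi: float,
                   neighbors) -> tuple[float, float]:
    for t_n in neighbors or ():
        if t_n == t_trans:
            continue
        if lo < t_n < t_trans:
            lo = 0.5 * (t_trans + t_n)
        elif t_trans < t_n < hi:
            hi = 0.5 * (t_trans + t_n)
    return lo, hi


def fit_transition(trace: Trace, t_trans: float, halfwindow: float = 0.15,
                   neighbors=()) -> ErfFit:
    """Nonlinear least-squares erf fit of the edge at ``t_trans``.

    ``neighbors`` lists the times of other transitions; any neighbor inside
    the window shrinks it to the midpoint toward that neighbor. The window
    must retain at least 10 samples. On non-convergence the fit is flagged:
    the amplitude falls back to the level difference across the window and
    the time constant is reported missing (NaN).
    """
    lo, hi = _shrink_window(t_trans, t_trans - halfwindow, t_trans + halfwindow,
                            neighbors)
    i_lo = max(0, trace.time_to_index(lo))
    i_hi = min(len(trace) - 1, trace.time_to_index(hi))
    if i_hi - i_lo + 1 < 10:
        raise ValueError(
            f"fitting window at t={t_trans:.4f} s has fewer than 10 samples")
    tt = trace.times[i_lo:i_hi + 1]
    yy = trace.samples[i_lo:i_hi + 1]

    pre = yy[tt < t_trans]
    post = yy[tt >= t_trans]
    c0 = float(np.mean(pre)) if pre.size else float(yy[0])
    post_mean = float(np.mean(post)) if post.size else float(yy[-1])
    a0 = 0.5 * (post_mean - c0)
    c0_mid = 0.5 * (post_mean + c0)
    dt = 1.0 / trace.sampling_rate
    t_bound = min(halfwindow / 3.0, 0.05)

    def _attempt(b0):
        popt, _ = curve_fit(
            _erf_model, tt, yy,
            p0=[a0 if a0 != 0 else 1e-3, b0, c0_mid, t_trans],
            bounds=([-np.inf, dt * 1e-4, -np.inf, t_trans - t_bound],
                    [np.inf, MAX_TC_S, np.inf, t_trans + t_bound]),
            maxfev=10000,
        )
        resid = yy - _erf_model(tt, *popt)
        return popt, float(np.sqrt(np.mean(resid ** 2)))

    for b0 in (1e-3, 1e-2, 5e-2):
        try:
            popt, rms = _attempt(b0)
            return ErfFit(A=float(popt[0]), B=float(abs(popt[1])),
                          C=float(popt[2]), t_center=float(popt[3]),
                          window=(float(tt[0]), float(tt[-1])),
                          residual_rms=rms, converged=True)
    # bounded restarts exhausted: flag and fall back to the level difference
        except RuntimeError:
            continue
    log.warning("erf fit did not converge at t=%.4f s; falling back to "
                "level difference", t_trans)
    return ErfFit(A=a0, B=float("nan"), C=c0_mid, t_center=t_trans,
                  window=(float(tt[0]), float(tt[-1])),
                  residual_rms=float(np.sqrt(np.var(yy))), converged=False)


def _erf_pair_model(t, a1, b1, tc1, a2, b2, tc2, c):
    return a1 * erf((t - tc1) / b1) + a2 * erf((t - tc2) / b2) + c


def fit_transition_pair(trace: Trace, t1: float, t2: float,
                        halfwindow: float = 0.15) -> tuple[ErfFit, ErfFit]:
    """Joint two-erf fit for transitions too close to window separately."""
    if t2 < t1:
        t1, t2 = t2, t1
    lo = t1 - halfwindow
    hi = t2 + halfwindow
    i_lo = max(0, trace.time_to_index(lo))
    i_hi = min(len(trace) - 1, trace.time_to_index(hi))
    if i_hi - i_lo + 1 < 10:
        raise ValueError("joint fitting window has fewer than 10 samples")
    tt = trace.times[i_lo:i_hi + 1]
    yy = trace.samples[i_lo:i_hi + 1]
    dt = 1.0 / trace.sampling_rate
    pre = yy[tt < t1]
    mid = yy[(tt >= t1) & (tt < t2)]
    post = yy[tt >= t2]
    y0 = float(np.mean(pre)) if pre.size else float(yy[0])
    y1 = float(np.mean(mid)) if mid.size else 0.5 * (yy[0] + yy[-1])
    y2 = float(np.mean(post)) if post.size else float(yy[-1])
    t_bound = min(halfwindow / 3.0, 0.05)
    p0 = [0.5 * (y1 - y0), 1e-3, t1, 0.5 * (y2 - y1), 1e-3, t2,
          0.5 * (y0 + y2)]
    lo_b = [-np.inf, dt * 1e-4, t1 - t_bound, -np.inf, dt * 1e-4, t2 - t_bound,
            -np.inf]
    hi_b = [np.inf, MAX_TC_S, t1 + t_bound, np.inf, MAX_TC_S, t2 + t_bound,
            np.inf]
    popt, _ = curve_fit(_erf_pair_model, tt, yy, p0=p0, bounds=(lo_b, hi_b),
                        maxfev=20000)
    resid = yy - _erf_pair_model(tt, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    window = (float(tt[0]), float(tt[-1]))
    f1 = ErfFit(A=float(popt[0]), B=float(abs(popt[1])), C=float(popt[6]),
                t_center=float(popt[2]), window=window, residual_rms=rms)
    f2 = ErfFit(A=float(popt[3]), B=float(abs(popt[4])), C=float(popt[6]),
                t_center=float(popt[5]), window=window, residual_rms=rms)
    return f1, f2


def classify_state(event: TransitionEvent, components) -> str:
    """Assign an event to a conductance state by the 1-SD interval rule.

    ``components`` carry ``mean`` and ``sd`` in pS. The event belongs to the
    component whose ``[mean - sd, mean + sd]`` interval contains its
    conductance; outside every interval it is unclassified; inside several,
    the nearest mean in SD units wins. The component with the largest mean
    is the fully open ("main") state, the smallest the substate.
    """
    if not components:
        raise ValueError("components must be non-empty")
    comps = sorted(components, key=lambda c: c.mean)
    labels = {id(comps[-1]): "main", id(comps[0]): "substate"}
    g = event.conductance_ps
    hits = [c for c in comps if c.mean - c.sd <= g <= c.mean + c.sd]
    if not hits:
        return "unclassified"
    best = min(hits, key=lambda c: abs(g - c.mean) / max(c.sd, 1e-12))
    return labels.get(id(best), f"state{comps.index(best)}")
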