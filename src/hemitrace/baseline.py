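"""Baseline drift isolation and removal.

Slow drift of the holding current is separated from channel gating by
subtracting an idealized event trace (the cumulative sum of fitted transition
steps, rendered as erf edges) from the raw record, fitting the remainder to
one of four function families, and subtracting the fitted drift:

* single exponential  ``a (1 - exp(-x/b)) + c``
* double exponential  ``a (1 - exp(-x/b)) + c (1 - exp(-x/d)) + e``
* logarithmic         ``a ln(x + c) + b``
* linear              ``a x + b``

The winning family is chosen by AIC; the corrected trace is then re-analyzed
(detection, refinement, erf fitting) and the loop repeats until the event set
stabilizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf

from .trace import Trace

__all__ = [
    "BaselineFamily",
    "BASELINE_FAMILIES",
    "BaselineModel",
    "IdealizedTrace",
    "build_idealized",
    "fit_baseline",
    "correct_and_reanalyze",
    "ReanalysisResult",
]

log = logging.getLogger(__name__)


def _single_exp(x, a, b, c):
    return a * (1.0 - np.exp(-x / b)) + c


def _double_exp(x, a, b, c, d, e):
    return a * (1.0 - np.exp(-x / b)) + c * (1.0 - np.exp(-x / d)) + e


def _log(x, a, b, c):
    return a * np.log(x + c) + b


def _linear(x, a, b):
    return a * x + b


@dataclass(frozen=True)
class BaselineFamily:
    name: str
    func: Callable
    param_names: tuple

    def initial_guess(self, x: np.ndarray, y: np.ndarray) -> list[float]:
        span = max(x[-1] - x[0], 1e-9)
        rng_y = y[-1] - y[0]
        if self.name == "single_exp":
            return [rng_y if rng_y != 0 else np.ptp(y) + 1e-9, span / 3.0, y[0]]
        if self.name == "double_exp":
            amp = rng_y if rng_y != 0 else np.ptp(y) + 1e-9
            return [amp / 2.0, span / 6.0, amp / 2.0, span / 2.0, y[0]]
        if self.name == "log":
            c0 = max(x[1] - x[0], 1e-6) if x.size > 1 else 1e-3
            design = np.column_stack([np.log(x + c0), np.ones_like(x)])
            ab, *_ = np.linalg.lstsq(design, y, rcond=None)
            return [ab[0], ab[1], c0]
        if self.name == "linear":
            a, b = np.polyfit(x, y, 1)
            return [a, b]
        raise KeyError(self.name)

    def bounds(self) -> tuple:
        if self.name == "log":
            # x + c must stay positive over the span (x >= 0)
            lo = [-np.inf, -np.inf, 1e-9]
            hi = [np.inf, np.inf, np.inf]
            return lo, hi
        if self.name in ("single_exp", "double_exp"):
            n = len(self.param_names)
            lo = [-np.inf] * n
            hi = [np.inf] * n
            for i, p in enumerate(self.param_names):
                if p in ("b", "d"):  # time constants positive
                    lo[i] = 1e-6
            return lo, hi
        return (-np.inf, np.inf)


BASELINE_FAMILIES: dict[str, BaselineFamily] = {
    "single_exp": BaselineFamily("single_exp", _single_exp, ("a", "b", "c")),
    "double_exp": BaselineFamily("double_exp", _double_exp, ("a", "b", "c", "d", "e")),
    "log": BaselineFamily("log", _log, ("a", "b", "c")),
    "linear": BaselineFamily("linear", _linear, ("a", "b")),
}


@dataclass
class BaselineModel:
    """A fitted drift function: family name, coefficients, and fit scores."""

    family: str
    params: dict
    fit_rss: float
    aic: float
    alternatives: dict = field(default_factory=dict)  # family -> (params, rss, aic)

    def evaluate(self, trace_or_times) -> np.ndarray:
        """Drift value at each sample time (x measured from the trace start)."""
        if isinstance(trace_or_times, Trace):
            x = trace_or_times.times - trace_or_times.t0
        else:
            x = np.asarray(trace_or_times, dtype=float)
        if self.family == "constant":
            return np.full_like(x, self.params["a"], dtype=float)
        fam = BASELINE_FAMILIES[self.family]
        return fam.func(x, *[self.params[p] for p in fam.param_names])


@dataclass
class IdealizedTrace:
    """Noise-free piecewise reconstruction of channel levels."""

    samples: np.ndarray
    source_events: list


def build_idealized(trace: Trace, events: Sequence) -> IdealizedTrace:
    """Cumulative sum of signed transition steps, rendered as erf edges.

    Each event contributes ``(step/2) * (1 + erf((t - t_trans)/B))`` where
    ``step`` is ``+a_trans`` for openings and ``-a_trans`` for closings and
    ``B`` the event's fitted time constant (events without a usable time
    constant are rendered as near-instantaneous steps). Subtracting the
    result from the raw trace leaves drift plus noise.
    """
    times = trace.times
    out = np.zeros_like(times)
    events = sorted(events, key=lambda ev: ev.t_trans)
    level_sign = 1.0 if trace.vm >= 0 else -1.0
    # tolerance for the below-zero-channels check: amplitude estimates of an
    # open/close pair differ by fit noise, so only a deficit approaching a
    # whole event amplitude suggests a missed closing
    amp_scale = float(np.median([abs(ev.a_trans_pa) for ev in events])) \
        if events else 0.0
    cum = 0.0
    for ev in events:
        sign = 1.0 if ev.direction == "opening" else -1.0
        delta = sign * abs(ev.a_trans_pa) * level_sign
        cum += delta
        if level_sign * cum < -0.45 * amp_scale:
            warnings.warn(
                f"idealized level below zero channels at t={ev.t_trans:.3f} s "
                "(possible missed closing)", stacklevel=2)
        tc_ms = getattr(ev, "tc_trans_ms", None)
        b = max((tc_ms or 0.0) * 1e-3, 1e-12) if tc_ms == tc_ms and tc_ms else 1e-12
        span = 8.0 * b
        i0 = int(np.searchsorted(times, ev.t_trans - span))
        i1 = int(np.searchsorted(times, ev.t_trans + span))
        if i1 > i0:
            out[i0:i1] += 0.5 * delta * (1.0 + erf((times[i0:i1] - ev.t_trans) / b))
        out[i1:] += delta
    return IdealizedTrace(samples=out, source_events=list(events))


def _aic(n: int, rss: float, k: int) -> float:
    # Gaussian log-likelihood AIC; +1 for the implicit noise variance
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)


def fit_baseline(residual: Trace, max_points: int = 8000) -> BaselineModel:
    """Fit all four drift families to an event-free residual; pick by AIC.

    Long records are decimated to at most ``max_points`` samples before the
    nonlinear fits (the drift families are smooth on the seconds scale, so
    decimation does not change the fitted coefficients). All families are
    retained in ``alternatives`` for inspection; a family that fails to
    converge is skipped, and if every family fails a constant (mean) baseline
    is returned with a warning.
    """
    x_full = residual.times - residual.t0
    y_full = residual.samples
    min_len = 10 * max(len(f.param_names) for f in BASELINE_FAMILIES.values())
    if y_full.size < min_len:
        raise ValueError(f"residual too short for baseline fitting "
                         f"({y_full.size} < {min_len} samples)")
    step = max(1, y_full.size // max_points)
    x, y = x_full[::step], y_full[::step]

    results: dict[str, tuple[dict, float, float]] = {}
    for name, fam in BASELINE_FAMILIES.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(fam.func, x, y, p0=fam.initial_guess(x, y),
                                    bounds=fam.bounds(), maxfev=20000)
            pred = fam.func(x, *popt)
            rss = float(np.sum((y - pred) ** 2))
            if not np.isfinite(rss):
                raise RuntimeError("non-finite fit")
            params = dict(zip(fam.param_names, (float(v) for v in popt)))
            results[name] = (params, rss, _aic(y.size, rss, len(popt)))
        except Exception as exc:  # non-convergence: skip this family
            log.debug("baseline family %s failed: %s", name, exc)
    if not results:
        warnings.warn("all baseline families failed; using constant baseline",
                      stacklevel=2)
        mean = float(np.mean(y))
        rss = float(np.sum((y - mean) ** 2))
        return BaselineModel("constant", {"a": mean}, rss, _aic(y.size, rss, 1))

    best = min(results, key=lambda k: results[k][2])
    params, rss, aic = results[best]
    return BaselineModel(best, params, rss, aic, alternatives=results)


@dataclass
class ReanalysisResult:
    corrected: Trace
    events: list
    baseline: BaselineModel
    converged: bool
    n_cycles: int


def _same_event_set(a: Sequence, b: Sequence, tol_samples: float,
                    sampling_rate: float) -> bool:
    if len(a) != len(b):
        return False
    tol = tol_samples / sampling_rate
    for ea, eb in zip(a, b):
        if ea.direction != eb.direction or abs(ea.t_trans - eb.t_trans) > tol:
            return False
    return True


def correct_and_reanalyze(trace: Trace, config, initial_events: Sequence,
                          max_cycles: int = 5) -> ReanalysisResult:
    """Iterate {subtract baseline, re-detect, re-fit, re-build, re-fit drift}.

    Starts from an already-completed detection pass (``initial_events``) and
    loops until the event set is unchanged between successive cycles (same
    count, directions, and times within 2 samples) or ``max_cycles`` is hit,
    in which case the last iteration is returned flagged non-converged.
    """
    from .pipeline import detect_and_fit  # late import: pipeline orchestrates us

    events = list(initial_events)
    corrected = trace
    model = None
    converged = False
    for cycle in range(1, max_cycles + 1):
        ideal = build_idealized(trace, events)
        residual = trace.with_samples(trace.samples - ideal.samples)
        model = fit_baseline(residual)
        corrected = trace.with_samples(trace.samples - model.evaluate(trace))
        new_events = detect_and_fit(corrected, config)
        if _same_event_set(events, new_events, 2.0, trace.sampling_rate):
            events = new_events
            converged = True
            break
        events = new_events
    else:
        cycle = max_cycles
        log.warning("baseline reanalysis did not converge in %d cycles", max_cycles)
    return ReanalysisResult(corrected=corrected, events=events, baseline=model,
                            converged=converged, n_cycles=cycle)
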