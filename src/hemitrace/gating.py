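"""Per-trace gating physiology: conductance conversion, nominal open
probability (NPo), and transition counts by state class.

NPo (number of active channels x open probability) is estimated from a
baseline-corrected trace by placing the open-closed discriminator half-way
between baseline and the fully open level and accumulating the time spent
above it; time spent above multiples of the open level contributes
multiplicatively (stacked channels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fitting import classify_state
from .trace import Trace

__all__ = [
    "GatingSummary",
    "to_conductance",
    "compute_npo",
    "count_transitions",
    "transition_fold_report",
]

log = logging.getLogger(__name__)


@dataclass
class GatingSummary:
    """Per-trace gating statistics."""

    npo: float = 0.0
    open_time_s: float = 0.0
    recording_time_s: float = 0.0
    n_transitions_total: int = 0
    n_main: int = 0
    n_substate: int = 0
    n_unclassified: int = 0
    transitions_per_30s: float = 0.0
    npo_reliable: bool = True


def to_conductance(delta_i: float, vm: float):
    """Unitary conductance gamma = delta_i / Vm, reported in pS.

    ``delta_i`` in pA and ``vm`` in mV give nS; the result is scaled to pS.
    Accepts scalars or arrays; raises if ``vm`` is 0.
    """
    if vm == 0:
        raise ValueError("vm must be nonzero to convert current to conductance")
    return 1000.0 * np.asarray(delta_i, dtype=float) / vm if np.ndim(delta_i) \
        else 1000.0 * delta_i / vm


def compute_npo(corrected: Trace, open_level_pa: float,
                threshold_fraction: float = 0.5,
                min_open_s: float = 0.001) -> GatingSummary:
    """NPo by the half-way discriminator rule on a baseline-corrected trace.

    The threshold sits at ``threshold_fraction x open_level_pa`` above
    baseline (taken as 0 after correction). A sample above the threshold
    counts as >= 1 open channel; each further ``open_level_pa`` of current
    counts one more stacked channel. Above-threshold excursions shorter
    than ``min_open_s`` (default 1 ms) are discarded as noise, so a flat
    noisy trace scores exactly zero. NPo is the occupancy-weighted open
    time divided by the recording time.
    """
    if not open_level_pa > 0:
        raise ValueError("open_level_pa must be > 0")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    vsign = 1.0 if corrected.vm >= 0 else -1.0
    s = corrected.samples * vsign
    dt = 1.0 / corrected.sampling_rate
    thr = threshold_fraction * open_level_pa

    noise_sd = float(np.median(np.abs(np.diff(s)))) / (0.6745 * np.sqrt(2.0))
    reliable = bool(open_level_pa > 3.0 * noise_sd)
    if not reliable:
        log.warning("open level (%.3g pA) is within the noise floor "
                    "(%.3g pA SD); NPo unreliable", open_level_pa, noise_sd)

    above = s > thr
    # debounce: drop above-threshold runs shorter than min_open_s
    min_samples = max(1, int(round(min_open_s * corrected.sampling_rate)))
    if min_samples > 1 and above.any():
        padded = np.r_[False, above, False].astype(int)
        edges = np.flatnonzero(np.diff(padded))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start < min_samples:
                above[start:stop] = False
    levels = np.zeros_like(s)
    levels[above] = np.floor((s[above] - thr) / open_level_pa) + 1.0
    recording = s.size * dt
    return GatingSummary(
        npo=float(np.sum(levels) * dt / recording),
        open_time_s=float(np.count_nonzero(above) * dt),
        recording_time_s=recording,
        npo_reliable=reliable,
    )


def count_transitions(events, components, window_s: float = 30.0,
                      recording_time_s: float | None = None) -> dict:
    """Tally transitions per state class, normalized per ``window_s``.

    Events still ``pending`` are classified against ``components`` first.
    Counts are reported per recording and as a rate per the nominal 30 s
    window for comparability across sweep lengths.
    """
    n_main = n_sub = n_uncl = 0
    for ev in events:
        cls = ev.state_class
        if cls == "pending":
            cls = classify_state(ev, components)
            ev.state_class = cls
        if cls == "main":
            n_main += 1
        elif cls == "substate":
            n_sub += 1
        else:
            n_uncl += 1
    total = n_main + n_sub + n_uncl
    if recording_time_s:
        per_window = total * window_s / recording_time_s
    else:
        per_window = float(total)
    return {
        "n_transitions_total": total,
        "n_main": n_main,
        "n_substate": n_sub,
        "n_unclassified": n_uncl,
        "transitions_per_30s": per_window,
    }


def transition_fold_report(reference: tuple, test: tuple) -> dict:
    """Fold changes between two conditions from per-trace transition counts.

    ``reference`` and ``test`` are ``(main, substate)`` mean transition
    counts per 30 s trace. Returns the main-state fold reduction
    (reference/test), the substate fold increase (test/reference), the
    overall transition-frequency fold (reference total / test total), and
    the count-based substate fractions of both conditions with their fold.
    """
    ref_main, ref_sub = reference
    test_main, test_sub = test
    ref_total = ref_main + ref_sub
    test_total = test_main + test_sub
    frac_ref = ref_sub / ref_total if ref_total else float("nan")
    frac_test = test_sub / test_total if test_total else float("nan")
    return {
        "main_fold_decrease": ref_main / test_main if test_main else float("inf"),
        "substate_fold_increase": test_sub / ref_sub if ref_sub else float("inf"),
        "total_fold_decrease": ref_total / test_total if test_total else float("inf"),
        "substate_fraction_reference": frac_ref,
        "substate_fraction_test": frac_test,
        "substate_fraction_fold": frac_test / frac_ref if frac_ref else float("inf"),
    }
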