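"""Shared test helpers: synthetic edges and ground-truth event matching."""

import numpy as np

import hemitrace as ht


def make_erf_edge(a=10.0, b_ms=5.0, c=0.0, t0=1.0, fs=4000.0, dur=2.0,
                  noise=0.0, seed=0, vm=70.0):
    """Single erf edge f(t) = a*erf((t-t0)/b) + c, optionally noisy."""
    from scipy.special import erf
    t = np.arange(int(dur * fs)) / fs
    y = a * erf((t - t0) / (b_ms * 1e-3)) + c
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0, noise, t.size)
    return ht.Trace(samples=y, sampling_rate=fs, vm=vm)


def match_events(detected, truth_events, vm=70.0, tol_s=0.05):
    """Greedy matching of detected events to ground truth by time+direction.

    Returns (matched pairs, unmatched truth, unmatched detected).
    """
    taken = set()
    pairs = []
    missed = []
    for te in sorted(truth_events, key=lambda e: e.time_s):
        want = "opening" if te.direction > 0 else "closing"
        cands = [(i, ev) for i, ev in enumerate(detected)
                 if i not in taken and ev.direction == want
                 and abs(ev.t_trans - te.time_s) < tol_s]
        if cands:
            i, ev = min(cands, key=lambda c: abs(c[1].t_trans - te.time_s))
            taken.add(i)
            pairs.append((te, ev))
        else:
            missed.append(te)
    extra = [ev for i, ev in enumerate(detected) if i not in taken]
    return pairs, missed, extra
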