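"""Ground-truth-labelled synthetic unitary current traces.

The generator emulates the statistical structure the analysis assumes:
three-level gating (closed, ~80 pS substate, ~217 pS fully open state),
error-function shaped transition edges with exponentially distributed time
constants, stacked activity of several independent channels, i.i.d. Gaussian
background noise specified as a conductance-equivalent SD, and slow baseline
drift drawn from one of four function families.

Gating schedule (per channel)
-----------------------------
Opening attempts arrive as a Poisson process with rate ``transition_rate``;
an attempt is accepted only while the channel is closed and at least
``min_dwell`` seconds after the previous transition. Each accepted opening
draws a state (substate with probability ``substate_fraction``, otherwise the
fully open state), a conductance from that state's Gaussian, and an open
sojourn of ``min_dwell + Exp(dwell_mean - min_dwell)`` seconds, after which
the matching closing is emitted. The minimum sojourn is a consistency
constraint of the signal model: transition edges are rendered as erf ramps
with time constants up to 300 ms, so sojourns shorter than an edge would not
correspond to completed, resolvable transitions.

Each transition is rendered as ``(delta/2) * (1 + erf((t - t0)/B))`` added to
the running level, i.e. a full step of ``delta`` pA centered at ``t0`` with
time constant ``B`` — the same functional form the fitting stage assumes, so
parameters are exactly identifiable at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import erf

from .baseline import BASELINE_FAMILIES
from .trace import Trace

__all__ = [
    "SimulationConfig",
    "GatingEvent",
    "GroundTruth",
    "simulate_trace",
    "simulate_cohort",
]

#: Longest rendered/fit transition, seconds (slowest transition observed in
#: the recordings this analysis targets; also the erf fitting window size).
MAX_TRANSITION_S = 0.3

#: Margin kept free of events at both trace ends, seconds.
EDGE_MARGIN_S = 0.5


@dataclass(frozen=True)
class GatingEvent:
    """One ground-truth transition."""

    time_s: float
    direction: int  # +1 opening, -1 closing
    amplitude_pa: float  # signed like vm: positive at positive potentials
    tc_ms: float  # erf time constant of the rendered edge
    state: str  # state label ("main", "substate", ...)
    channel: int = 0


@dataclass
class GroundTruth:
    """Everything injected into a simulated trace, for validation."""

    events: list[GatingEvent]
    baseline_samples: np.ndarray
    ideal_samples: np.ndarray  # noise- and drift-free piecewise-erf signal

    def occupancy(self, sampling_rate: float, n_samples: int) -> np.ndarray:
        """Per-sample open-channel count (edges counted at their centers)."""
        occ = np.zeros(n_samples)
        for ev in self.events:
            i = min(max(int(round(ev.time_s * sampling_rate)), 0), n_samples)
            occ[i:] += ev.direction
        return occ


@dataclass
class SimulationConfig:
    """Generative parameters for one simulated sweep.

    Defaults emulate a control-condition recording: a single channel stepped
    to +70 mV for 30 s at 4 kHz, 30 pS-equivalent Gaussian noise, gating
    between a 217 +/- 66 pS fully open state and an 80 +/- 28 pS substate
    (5.3% of events), edge time constants exponential with 5.2 ms mean, and
    rates tuned to ~14.5 transitions per 30 s trace.
    """

    duration: float = 30.0  # s
    sampling_rate: float = 4000.0  # Hz
    vm: float = 70.0  # mV
    noise_sd: float = 30.0  # pS-equivalent; pA SD = noise_sd * |vm| / 1000
    n_channels: int = 1
    state_levels: tuple = (("substate", 80.0, 28.0), ("main", 217.0, 66.0))
    transition_rate: float = 0.36  # opening attempts / s / channel
    tc_tau: float = 5.2  # ms, mean of the edge time-constant distribution
    substate_fraction: float = 0.053
    dwell_mean: float = 1.0  # s, mean open sojourn
    min_dwell: float = 0.35  # s, minimum sojourn / closed refractory
    baseline_family: str = "none"
    baseline_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if self.vm == 0:
            raise ValueError("vm must be nonzero (noise and amplitudes are "
                             "specified in pS and converted via vm)")
        if not 0 <= self.substate_fraction <= 1:
            raise ValueError("substate_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.transition_rate < 0:
            raise ValueError("transition_rate must be >= 0")
        if not self.tc_tau > 0:
            raise ValueError("tc_tau must be > 0")
        if not 0 <= self.min_dwell < self.dwell_mean:
            raise ValueError("min_dwell must satisfy 0 <= min_dwell < dwell_mean")
        if not self.state_levels:
            raise ValueError("state_levels must be non-empty")
        for label, mean, sd in self.state_levels:
            if not mean > 0:
                raise ValueError(f"state_levels: conductance of {label!r} must be > 0")
            if sd < 0:
                raise ValueError(f"state_levels: SD of {label!r} must be >= 0")
        if self.baseline_family not in ("none", *BASELINE_FAMILIES):
            raise ValueError(
                f"baseline_family must be one of "
                f"{('none', *BASELINE_FAMILIES)}, got {self.baseline_family!r}")

    # -- condition presets -------------------------------------------------

    @classmethod
    def control(cls, **overrides) -> "SimulationConfig":
        """HeLa-Cx43 control condition (the class defaults)."""
        return cls(**overrides)

    @classmethod
    def gap19(cls, **overrides) -> "SimulationConfig":
        """Gap19-treated condition: sparser gating, 34.7% substate events,
        slowed substate kinetics (biexponential tc mix handled via tc_tau
        per state in :func:`draw_tc`)."""
        params = dict(transition_rate=0.111, substate_fraction=0.347)
        params.update(overrides)
        return cls(**params)

    @classmethod
    def egfp(cls, **overrides) -> "SimulationConfig":
        """EGFP-tagged condition: near-control activity, slower edges."""
        params = dict(transition_rate=0.33, tc_tau=13.9)
        params.update(overrides)
        return cls(**params)


def _draw_conductance(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian conductance truncated to stay physical (> 1 pS)."""
    g = rng.normal(mean, sd)
    while g <= 1.0:
        g = rng.normal(mean, sd)
    return g


def _draw_tc(rng: np.random.Generator, tau_ms: float) -> float:
    """Exponential edge time constant truncated at the 300 ms maximum."""
    tc = rng.exponential(tau_ms)
    while tc > MAX_TRANSITION_S * 1e3:
        tc = rng.exponential(tau_ms)
    return tc


def _schedule_channel(config: SimulationConfig, rng: np.random.Generator,
                      channel: int) -> list[GatingEvent]:
    """Generate the gating schedule of one channel (no waveform rendering)."""
    if config.transition_rate == 0:
        return []
    substates = [s for s in config.state_levels]
    sub = min(substates, key=lambda s: s[1])
    main = max(substates, key=lambda s: s[1])
    t_last_open = config.duration - EDGE_MARGIN_S - config.min_dwell
    t_end = config.duration - EDGE_MARGIN_S + 0.1
    events: list[GatingEvent] = []
    t = EDGE_MARGIN_S
    t_free = EDGE_MARGIN_S
    while True:
        t += rng.exponential(1.0 / config.transition_rate)
        if t > t_last_open:
            break
        if t < t_free:
            continue  # channel open or refractory: attempt discarded
        if len(config.state_levels) == 1 or rng.random() >= config.substate_fraction:
            label, mean, sd = main
        else:
            label, mean, sd = sub
        g = _draw_conductance(rng, mean, sd)
        amp = g * config.vm / 1000.0  # pS * mV -> pA (signed like vm)
        dwell = config.min_dwell + rng.exponential(
            config.dwell_mean - config.min_dwell)
        t_close = min(t + dwell, t_end)
        events.append(GatingEvent(t, +1, amp, _draw_tc(rng, config.tc_tau),
                                  label, channel))
        events.append(GatingEvent(t_close, -1, amp, _draw_tc(rng, config.tc_tau),
                                  label, channel))
        t_free = t_close + config.min_dwell
    return events


def _render_events(events: Sequence[GatingEvent], times: np.ndarray) -> np.ndarray:
    """Sum of erf edges: each event adds (delta/2)(1 + erf((t - t0)/B))."""
    out = np.zeros_like(times)
    n = times.size
    if n == 0:
        return out
    dt = times[1] - times[0] if n > 1 else 1.0
    for ev in events:
        delta = ev.direction * ev.amplitude_pa
        b = max(ev.tc_ms * 1e-3, 1e-12)
        span = 8.0 * b
        i0 = int(np.searchsorted(times, ev.time_s - span))
        i1 = int(np.searchsorted(times, ev.time_s + span))
        if i1 > i0:
            out[i0:i1] += 0.5 * delta * (1.0 + erf((times[i0:i1] - ev.time_s) / b))
        out[i1:] += delta
    return out


def _render_baseline(config: SimulationConfig, times: np.ndarray) -> np.ndarray:
    if config.baseline_family == "none":
        return np.zeros_like(times)
    family = BASELINE_FAMILIES[config.baseline_family]
    missing = [p for p in family.param_names if p not in config.baseline_params]
    if missing:
        raise ValueError(
            f"baseline_params missing {missing} for family {config.baseline_family!r}")
    args = [config.baseline_params[p] for p in family.param_names]
    return family.func(times - times[0], *args)


def simulate_trace(config: SimulationConfig) -> tuple[Trace, GroundTruth]:
    """Simulate one sweep: gating edges, then Gaussian noise, then drift.

    Returns the trace and the full ground truth (event list, injected drift,
    and the noise-free ideal signal).
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sampling_rate))
    times = np.arange(n) / config.sampling_rate

    events: list[GatingEvent] = []
    for ch in range(config.n_channels):
        events.extend(_schedule_channel(config, rng, ch))
    events.sort(key=lambda ev: ev.time_s)

    ideal = _render_events(events, times)
    noise_sd_pa = config.noise_sd * abs(config.vm) / 1000.0
    noise = rng.normal(0.0, noise_sd_pa, n) if noise_sd_pa > 0 else np.zeros(n)
    drift = _render_baseline(config, times)

    trace = Trace(
        samples=ideal + noise + drift,
        sampling_rate=config.sampling_rate,
        vm=config.vm,
        metadata={"seed": config.seed, "synthetic": True},
    )
    return trace, GroundTruth(events=events, baseline_samples=drift,
                              ideal_samples=ideal)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Per-trace seeds from one master seed via SeedSequence spawning."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def simulate_cohort(config: SimulationConfig, n_traces: int,
                    seed: int) -> list[tuple[Trace, GroundTruth]]:
    """Simulate ``n_traces`` independent sweeps, reproducibly.

    Each trace uses a seed derived from ``seed`` by a fixed splitting rule
    (:func:`derive_seeds`), so the cohort is bit-reproducible and trace ``i``
    equals ``simulate_trace`` run with that derived seed.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    out = []
    for i, child_seed in enumerate(derive_seeds(seed, n_traces)):
        cfg = replace(config, seed=child_seed)
        trace, truth = simulate_trace(cfg)
        trace.metadata["trace_id"] = f"sim-{seed}-{i:03d}"
        out.append((trace, truth))
    return out
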