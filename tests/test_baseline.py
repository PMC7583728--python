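"""Idealized-trace construction, drift fitting, and the reanalysis loop."""

import dataclasses
import warnings

import numpy as np
import pytest

import hemitrace as ht
from hemitrace.baseline import BASELINE_FAMILIES

from conftest import match_events


def _trace(y, fs=4000.0, vm=70.0):
    return ht.Trace(samples=np.asarray(y, dtype=float), sampling_rate=fs, vm=vm)


def _event(t, direction, amp_pa, tc_ms=1.0):
    return ht.TransitionEvent(t_trans=t, direction=direction,
                              a_trans_pa=amp_pa,
                              conductance_ps=1000 * amp_pa / 70.0,
                              tc_trans_ms=tc_ms)


class TestBuildIdealized:
    def test_no_events_gives_zeros(self):
        tr = _trace(np.random.default_rng(0).normal(0, 1, 1000))
        ideal = ht.build_idealized(tr, [])
        np.testing.assert_array_equal(ideal.samples, 0.0)

    def test_open_close_pair_is_rectangular_pulse(self):
        tr = _trace(np.zeros(8000))
        events = [_event(0.5, "opening", 15.0, 0.5),
                  _event(1.5, "closing", 15.0, 0.5)]
        ideal = ht.build_idealized(tr, events)
        assert ideal.samples[0] == pytest.approx(0.0, abs=1e-9)
        assert ideal.samples[4000] == pytest.approx(15.0, abs=1e-9)
        assert ideal.samples[-1] == pytest.approx(0.0, abs=1e-9)

    def test_residual_noise_sd_matches_configured_noise(self):
        cfg = ht.SimulationConfig(seed=8)
        tr, truth = ht.simulate_trace(cfg)
        events = [
            _event(ev.time_s, "opening" if ev.direction > 0 else "closing",
                   abs(ev.amplitude_pa), ev.tc_ms)
            for ev in truth.events]
        ideal = ht.build_idealized(tr, events)
        resid_sd = np.std(tr.samples - ideal.samples)
        assert resid_sd == pytest.approx(30.0 * 70.0 / 1000.0, rel=0.10)

    def test_level_conservation_on_simulated_events(self):
        _, truth = ht.simulate_trace(ht.SimulationConfig(seed=8))
        signed = sum(ev.direction * ev.amplitude_pa for ev in truth.events
                     if ev.time_s)  # full open/close pairs cancel
        open_now = sum(ev.direction for ev in truth.events)
        if open_now == 0:
            assert abs(signed) < 1e-9

    def test_missed_closing_warns(self):
        tr = _trace(np.zeros(8000))
        events = [_event(0.5, "closing", 15.0)]
        with pytest.warns(UserWarning, match="missed closing"):
            ht.build_idealized(tr, events)


class TestFitBaseline:
    def test_linear_ramp_recovered_against_closed_form(self):
        rng = np.random.default_rng(1)
        fs, dur = 1000.0, 30.0
        t = np.arange(int(fs * dur)) / fs
        y = 1.7 * t + 3.0 + rng.normal(0, 2.0, t.size)
        model = ht.fit_baseline(_trace(y, fs))
        assert model.family == "linear"
        slope_oracle = np.polyfit(t, y, 1)[0]
        assert model.params["a"] == pytest.approx(slope_oracle, rel=0.02)
        assert model.params["a"] == pytest.approx(1.7, rel=0.02)

    def test_single_exp_identified_exactly_at_zero_noise(self):
        fs, dur = 1000.0, 30.0
        t = np.arange(int(fs * dur)) / fs
        y = 50.0 * (1.0 - np.exp(-t / 5.0)) + 2.0
        model = ht.fit_baseline(_trace(y, fs))
        assert model.family == "single_exp"
        assert model.params["a"] == pytest.approx(50.0, rel=1e-4)
        assert model.params["b"] == pytest.approx(5.0, rel=1e-4)
        assert model.params["c"] == pytest.approx(2.0, abs=1e-3)

    def test_flat_residual_leaves_trace_unchanged(self):
        rng = np.random.default_rng(2)
        tr = _trace(rng.normal(0, 2.0, 30000), fs=1000.0)
        model = ht.fit_baseline(tr)
        corr = tr.samples - model.evaluate(tr)
        assert np.std(corr) == pytest.approx(np.std(tr.samples), rel=0.01)
        assert abs(np.mean(corr)) < 0.1

    def test_converged_families_retained_for_inspection(self):
        rng = np.random.default_rng(9)
        t = np.arange(30000) / 1000.0
        y = 8.0 * np.log(t + 0.5) + rng.normal(0, 1.0, t.size)
        model = ht.fit_baseline(_trace(y, fs=1000.0))
        # every family that converged is kept, winner included
        assert model.family in model.alternatives
        assert set(model.alternatives) <= set(BASELINE_FAMILIES)
        assert len(model.alternatives) >= 3

    def test_correction_is_idempotent(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        rng = np.random.default_rng(3)
        y = 40.0 * (1.0 - np.exp(-t / 6.0)) + rng.normal(0, 2.0, t.size)
        tr = _trace(y, fs)
        first = ht.fit_baseline(tr)
        corrected = tr.with_samples(tr.samples - first.evaluate(tr))
        second = ht.fit_baseline(corrected)
        # refitting the corrected residual finds only noise-scale structure
        assert np.ptp(second.evaluate(corrected)) < 3 * 2.0 / np.sqrt(fs)

    def test_too_short_residual_rejected(self):
        with pytest.raises(ValueError):
            ht.fit_baseline(_trace(np.zeros(20)))


DRIFT_CASES = [
    ("linear", {"a": 1.5, "b": 0.0}),
    ("single_exp", {"a": 50.0, "b": 5.0, "c": 0.0}),
    ("double_exp", {"a": 30.0, "b": 3.0, "c": 25.0, "d": 10.0, "e": 0.0}),
    ("log", {"a": 8.0, "b": 0.0, "c": 0.5}),
]


class TestCorrectAndReanalyze:
    def test_drift_free_trace_converges_in_one_extra_cycle(self):
        trace, _ = ht.simulate_trace(ht.SimulationConfig(seed=3))
        config = ht.PipelineConfig()
        events = ht.detect_and_fit(trace, config)
        rean = ht.correct_and_reanalyze(trace, config, events)
        assert rean.converged
        assert rean.n_cycles == 1
        assert len(rean.events) == len(events)

    def test_drift_only_trace_corrects_to_zero_mean(self):
        cfg = ht.SimulationConfig(seed=5, transition_rate=0.0,
                                  baseline_family="double_exp",
                                  baseline_params=DRIFT_CASES[2][1])
        trace, _ = ht.simulate_trace(cfg)
        config = ht.PipelineConfig()
        rean = ht.correct_and_reanalyze(trace, config, [])
        noise_sd = 30.0 * 70.0 / 1000.0
        assert abs(np.mean(rean.corrected.samples)) < 0.1 * noise_sd
        assert rean.events == []

    @pytest.mark.parametrize("family, params", DRIFT_CASES)
    def test_event_amplitudes_invariant_to_drift(self, family, params):
        # same gating schedule with and without drift: amplitudes within 2%
        base_cfg = ht.SimulationConfig(seed=6)
        drift_cfg = dataclasses.replace(base_cfg, baseline_family=family,
                                        baseline_params=params)
        config = ht.PipelineConfig()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_clean = ht.analyze_trace(ht.simulate_trace(base_cfg)[0], config)
            res_drift = ht.analyze_trace(ht.simulate_trace(drift_cfg)[0], config)
        truth = ht.simulate_trace(base_cfg)[1]
        pairs_c, _, _ = match_events(res_clean.events, truth.events)
        pairs_d, _, _ = match_events(res_drift.events, truth.events)
        amp_c = {round(te.time_s, 3): ev.a_trans_pa for te, ev in pairs_c}
        amp_d = {round(te.time_s, 3): ev.a_trans_pa for te, ev in pairs_d}
        shared = set(amp_c) & set(amp_d)
        assert len(shared) >= 0.9 * len(truth.events)
        for key in shared:
            assert amp_d[key] == pytest.approx(amp_c[key], rel=0.02)
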