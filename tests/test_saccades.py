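"""Saccade detection and scoring: oracle equivalence and task rules."""

import numpy as np
import pandas as pd
import pytest

from oculopheno import (DetectionParams, TaskSpec, TraceParams,
                        compute_vdi, detect_saccades, score_task, score_trial,
                        simulate_saccade_trace, summarize_participant,
                        velocity_trace)
from oculopheno.saccades import SaccadeEvent


def brute_force_detect(time_ms, pos, params):
    """Naive sample-by-sample reimplementation of the detection contract:
    smoothed central-difference velocity, threshold runs extended to local
    speed minima (bounded by the offset floor), gap merging, then duration
    and amplitude filters."""
    dt = time_ms[1] - time_ms[0]
    speed = np.abs(velocity_trace(pos, dt, params.smoothing_halfwidth_samples))
    n = len(speed)
    runs = []
    i = 0
    while i < n:
        if speed[i] >= params.velocity_threshold:
            j = i
            while j + 1 < n and speed[j + 1] >= params.velocity_threshold:
                j += 1
            a, b = i, j
            while a > 0 and speed[a - 1] < speed[a] \
                    and speed[a] >= params.offset_floor:
                a -= 1
            while b < n - 1 and speed[b + 1] < speed[b] \
                    and speed[b] >= params.offset_floor:
                b += 1
            runs.append((a, b))
            i = j + 1
        else:
            i += 1
    merged = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) * dt < params.merge_gap_ms:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        if (b - a) * dt < params.min_duration_ms:
            continue
        amp = pos[b] - pos[a]
        if abs(amp) < params.min_amplitude_deg:
            continue
        out.append((time_ms[a], time_ms[b], amp, speed[a:b + 1].max()))
    return out


class TestDetection:
    def test_constant_trace_yields_no_events(self):
        t = np.arange(0, 1000, 2.0)
        assert detect_saccades(t, np.full_like(t, 3.0)) == []

    def test_planted_step_onset_and_amplitude(self, clean_vg_trace,
                                              exact_detection):
        """Noiseless planted saccades: onset within one sample of the
        planted latency, amplitude within 0.1 degrees."""
        tr = clean_vg_trace
        for ann in tr.annotations.to_dict("records"):
            sel = (tr.time >= ann["trial_start_ms"]) & \
                (tr.time < ann["trial_end_ms"])
            evs = detect_saccades(tr.time[sel], tr.right_pos[sel],
                                  exact_detection)
            assert len(evs) == 2  # primary + refixation
            assert abs(evs[0].onset_ms - (ann["go_ms"] + 200.0)) <= 2.0
            assert abs(evs[0].amplitude - ann["target_deg"]) < 0.1

    def test_two_planted_saccades_ordered_with_correct_signs(self):
        t = np.arange(0, 1500, 2.0)
        pos = np.zeros_like(t)
        x1 = np.clip((t - 300) / 50, 0, 1)
        x2 = np.clip((t - 800) / 50, 0, 1)
        pos += 10 * 0.5 * (1 - np.cos(np.pi * x1))
        pos -= 6 * 0.5 * (1 - np.cos(np.pi * x2))
        evs = detect_saccades(t, pos)
        assert len(evs) == 2
        assert evs[0].onset_ms < evs[1].onset_ms
        assert evs[0].direction == "right" and evs[1].direction == "left"

    @pytest.mark.parametrize("noise_sd", [0.0, 0.05, 0.1])
    def test_matches_brute_force_oracle(self, noise_sd):
        """Vectorized detection equals the naive threshold-scan oracle."""
        params = DetectionParams()
        p = TraceParams(latency_ms=180, latency_sd=25, error_prob=0.3,
                        noise_sd=noise_sd, fep_frac_sd=0.1,
                        vdi_r_gain=1.3)
        tr = simulate_saccade_trace(TaskSpec("AS", 10), p, seed=17)
        for eye in (tr.left_pos, tr.right_pos):
            evs = detect_saccades(tr.time, eye, params)
            ref = brute_force_detect(tr.time, eye, params)
            assert len(evs) == len(ref)
            for ev, (on, off, amp, pv) in zip(evs, ref):
                assert ev.onset_ms == on and ev.offset_ms == off
                assert ev.amplitude == amp and ev.peak_velocity == pv

    def test_raising_threshold_never_adds_events_on_clean_traces(self):
        """On noiseless traces the event count is non-increasing in the
        threshold; on noisy traces only the supra-threshold sample count
        is guaranteed monotone (a velocity dip straddling two thresholds
        can split one event into two)."""
        p = TraceParams(latency_ms=200, latency_sd=30, noise_sd=0.0,
                        fep_frac_sd=0.0)
        tr = simulate_saccade_trace(TaskSpec("VG", 8), p, seed=23)
        thresholds = (20.0, 30.0, 60.0, 120.0, 240.0)
        counts = [len(detect_saccades(
            tr.time, tr.right_pos, DetectionParams(velocity_threshold=t)))
            for t in thresholds]
        assert counts == sorted(counts, reverse=True)

        noisy = simulate_saccade_trace(
            TaskSpec("VG", 8), TraceParams(latency_ms=200, latency_sd=30,
                                           noise_sd=0.1), seed=23)
        speed = np.abs(velocity_trace(noisy.right_pos, 2.0, 2))
        samples = [(speed >= t).sum() for t in thresholds]
        assert samples == sorted(samples, reverse=True)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 2.0, 5.0, 6.0, 8.0])
        with pytest.raises(ValueError, match="uniform"):
            detect_saccades(t, np.zeros(5))


def _event(onset, amp, direction=None):
    return SaccadeEvent(onset_ms=onset, offset_ms=onset + 40,
                        amplitude=amp, peak_velocity=300.0,
                        direction="right" if amp > 0 else "left")


def _ann(target, go=1000.0, stim=1000.0, fix_off=1000.0, resp_end=1800.0):
    return {"trial": 0, "target_deg": target, "go_ms": go,
            "stim_onset_ms": stim, "fix_off_ms": fix_off,
            "response_end_ms": resp_end}


class TestScoring:
    def test_antisaccade_toward_target_is_error(self):
        s = score_trial("AS", _ann(10.0), [_event(1200, 9.0)])
        assert s.is_error and np.isnan(s.latency_ms)

    def test_vg_latency_is_onset_minus_stimulus_onset(self):
        s = score_trial("VG", _ann(10.0), [_event(1180, 10.0)])
        assert s.latency_ms == pytest.approx(180.0)

    def test_memory_guided_delay_look_is_error(self):
        ann = _ann(10.0, go=3000.0, stim=800.0, fix_off=3000.0,
                   resp_end=3800.0)
        events = [_event(1100, 5.0), _event(3300, 10.0)]
        s = score_trial("MG", ann, events)
        assert s.is_error

    def test_memory_guided_small_delay_drift_not_error(self):
        ann = _ann(10.0, go=3000.0, stim=800.0, fix_off=3000.0,
                   resp_end=3800.0)
        events = [_event(1100, 1.5), _event(3300, 10.0)]
        s = score_trial("MG", ann, events)
        assert not s.is_error
        assert s.latency_ms == pytest.approx(300.0)

    def test_endogenously_cued_opposite_saccade_is_error(self):
        s = score_trial("EC", _ann(10.0), [_event(1150, -8.0)])
        assert s.is_error

    def test_ec_has_no_anticipatory_cutoff(self):
        s = score_trial("EC", _ann(10.0), [_event(1044, 10.0)])
        assert s.latency_ms == pytest.approx(44.0)

    def test_anticipatory_saccade_ignored_for_vg(self):
        s = score_trial("VG", _ann(10.0), [_event(1040, 10.0)])
        assert s.no_response  # only event falls below the 80 ms cutoff

    def test_no_saccade_flags_no_response(self):
        s = score_trial("AS", _ann(10.0), [])
        assert s.no_response and not s.is_error


class TestSummaries:
    def test_error_percentage_of_total_trials(self):
        scored = pd.DataFrame({
            "task": ["AS"] * 48,
            "is_error": [True] * 6 + [False] * 42,
            "no_response": [False] * 48,
            "latency_ms": [np.nan] * 6 + [300.0] * 42,
            "fep": [np.nan] * 48})
        out = summarize_participant(scored)
        assert out["AS_ERROR"] == pytest.approx(12.5)

    def test_latency_means_correct_trials_only(self):
        scored = pd.DataFrame({
            "task": ["VG"] * 3,
            "is_error": [False, False, True],
            "no_response": [False] * 3,
            "latency_ms": [150.0, 250.0, 90.0],
            "fep": [np.nan] * 3})
        assert summarize_participant(scored)["VG_LATENCY"] == 200.0

    def test_all_correct_gives_zero_error(self):
        scored = pd.DataFrame({"task": ["MG"] * 5, "is_error": [False] * 5,
                               "no_response": [False] * 5,
                               "latency_ms": [300.0] * 5,
                               "fep": [10.0] * 5})
        out = summarize_participant(scored)
        assert out["MG_ERROR"] == 0.0
        assert out["MG_FEP"] == 10.0

    def test_outcome_percentages_partition_trials(self):
        p = TraceParams(latency_ms=300, latency_sd=40, error_prob=0.3,
                        no_response_prob=0.1, noise_sd=0.05)
        tr = simulate_saccade_trace(TaskSpec("AS", 48), p, seed=31)
        sc = score_task(tr, "AS")
        assert len(sc) == 48
        n_err = sc.is_error.sum()
        n_nr = sc.no_response.sum()
        n_ok = (~sc.is_error & ~sc.no_response).sum()
        assert n_err + n_nr + n_ok == 48
        assert 0 <= 100 * n_err / 48 <= 100

    def test_planted_error_rate_recovered_within_binomial_error(self):
        """Scoring rules (not labels) reproduce the planted per-trial
        error probability across many antisaccade trials."""
        p_err = 0.25
        total, errors = 0, 0
        for seed in range(30):
            p = TraceParams(latency_ms=300, latency_sd=30, error_prob=p_err,
                            noise_sd=0.05, fep_frac_sd=0.15)
            tr = simulate_saccade_trace(TaskSpec("AS", 48), p, seed=seed)
            sc = score_task(tr, "AS")
            errors += sc.is_error.sum()
            total += len(sc)
        rate = errors / total
        se = np.sqrt(p_err * (1 - p_err) / total)
        assert abs(rate - p_err) < 3 * se


class TestRoundTrip:
    @pytest.mark.parametrize("task_id,n_trials", [
        ("VG", 12), ("AS", 16), ("MG", 10), ("EC", 16)])
    def test_planted_outcomes_recovered_exactly_without_noise(self, task_id,
                                                              n_trials):
        """With zero noise, planted error flags are recovered exactly and
        planted latencies to within the smoothing-induced onset bias."""
        from oculopheno import default_task_specs
        spec = default_task_specs()[task_id]
        spec = TaskSpec(task_id, n_trials, timing=spec.timing,
                        cue_validity=spec.cue_validity)
        p = TraceParams(latency_ms=260, latency_sd=40, error_prob=0.3,
                        noise_sd=0.0, fep_frac_sd=0.08)
        tr = simulate_saccade_trace(spec, p, seed=47)
        sc = score_task(tr, task_id).sort_values("trial")
        ann = tr.annotations.sort_values("trial")
        assert list(sc.is_error) == list(ann.true_error)
        both = ~sc.is_error.to_numpy() & ~sc.no_response.to_numpy()
        got = sc.latency_ms.to_numpy()[both]
        want = ann.true_latency_ms.to_numpy()[both]
        assert np.all(np.abs(got - want) <= 10.0)


class TestVDI:
    def test_identical_eyes_give_unit_ratio(self):
        p = TraceParams(latency_ms=180, latency_sd=10, noise_sd=0.0,
                        fep_frac_sd=0.0)
        tr = simulate_saccade_trace(TaskSpec("VG", 12), p, seed=3)
        assert np.array_equal(tr.left_pos, tr.right_pos)
        vdi_r, vdi_l = compute_vdi(tr)
        assert vdi_r == pytest.approx(1.0, abs=1e-12)
        assert vdi_l == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("gain", [1.03, 1.4, 2.0])
    def test_planted_gain_recovered(self, gain):
        p = TraceParams(latency_ms=180, latency_sd=10, noise_sd=0.0,
                        fep_frac_sd=0.0, vdi_r_gain=gain)
        tr = simulate_saccade_trace(TaskSpec("VG", 24), p, seed=5)
        vdi_r, _ = compute_vdi(tr)
        assert vdi_r == pytest.approx(gain, abs=1e-6)

    def test_healthy_simulation_within_control_range(self):
        """Default healthy traces land inside the published control VDI
        range (0.86 - 1.12 rightward)."""
        p = TraceParams(latency_ms=175, latency_sd=20, noise_sd=0.1,
                        fep_frac_sd=0.05, vdi_r_gain=1.03, vdi_l_gain=1.04)
        tr = simulate_saccade_trace(TaskSpec("VG", 24), p, seed=41)
        vdi_r, vdi_l = compute_vdi(tr)
        assert 0.86 <= vdi_r <= 1.12
        assert 0.86 <= vdi_l <= 1.17

    def test_direction_without_saccades_is_absent(self):
        p = TraceParams(latency_ms=180, noise_sd=0.0, fep_frac_sd=0.0)
        spec = TaskSpec("VG", 6)
        tr = simulate_saccade_trace(
            spec, TraceParams(latency_ms=180, noise_sd=0.0, fep_frac_sd=0.0,
                              trial_overrides={k: {"direction": 1.0}
                                               for k in range(6)}), seed=2)
        vdi_r, vdi_l = compute_vdi(tr)
        assert np.isfinite(vdi_r) and np.isnan(vdi_l)
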