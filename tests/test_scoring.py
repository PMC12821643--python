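"""RWA scoring chain: envelope, background, bursts, mini-epochs, epochs."""

import math

import numpy as np
import pytest

from rwahome.hypnogram import Hypnogram
from rwahome.scoring import (
    Burst,
    EnvelopeSeries,
    classify_patient,
    compute_envelope,
    detect_bursts,
    estimate_background,
    score_epochs,
    score_mini_epochs,
    score_recording,
)

RATE = 128.0


def _env(values, step=1.0 / RATE):
    return EnvelopeSeries(values=np.asarray(values, float), step=step)


class TestEnvelope:
    def test_zero_signal_gives_zero_envelope(self):
        env = compute_envelope(np.zeros(1000), RATE)
        assert np.allclose(env.values, 0.0)

    def test_pure_tone_amplitude_recovered(self):
        t = np.arange(int(8 * RATE)) / RATE
        a = 3.7
        x = a * np.sin(2 * np.pi * 30.0 * t)
        env = compute_envelope(x, RATE)
        core = env.values[int(RATE) : -int(RATE)]  # ignore filter edges
        assert np.median(core) == pytest.approx(a, rel=0.05)

    def test_linearity_under_positive_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        e1 = compute_envelope(x, RATE).values
        e2 = compute_envelope(3.5 * x, RATE).values
        assert np.allclose(e2, 3.5 * e1, rtol=1e-9)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_envelope(np.array([]), RATE)


class TestBackground:
    def test_constant_envelope_returns_constant(self):
        env = _env(np.full(5000, 2.5))
        assert estimate_background(env, scope="whole_night") == 2.5

    def test_trimmed_median_ignores_sparse_bursts(self):
        values = np.full(10_000, 1.0)
        values[::20] = 10.0  # 5% of samples at 10x
        assert estimate_background(_env(values), scope="whole_night") == 1.0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        v = rng.rayleigh(1.0, 5000)
        b1 = estimate_background(_env(v), scope="whole_night")
        b2 = estimate_background(_env(7.0 * v), scope="whole_night")
        assert b2 == pytest.approx(7.0 * b1, rel=1e-12)

    def test_all_zero_envelope_undefined(self):
        with pytest.raises(ValueError, match="undefined|zero"):
            estimate_background(_env(np.zeros(100)), scope="whole_night")

    def test_rem_scope_uses_only_rem_epochs(self):
        h = Hypnogram(np.array(["N2", "REM"], dtype=object))
        per_epoch = int(30 * RATE)
        values = np.concatenate([np.full(per_epoch, 9.0), np.full(per_epoch, 2.0)])
        assert estimate_background(_env(values), h, scope="rem") == 2.0


class TestBurstDetection:
    def test_flat_background_level_has_no_bursts(self):
        assert detect_bursts(_env(np.ones(1000)), background=1.0) == []

    def test_sub_minimum_excursion_rejected(self):
        values = np.ones(1000)
        values[500:506] = 10.0  # 6 samples = 47 ms < 0.1 s
        assert detect_bursts(_env(values), background=1.0) == []

    def test_overlong_run_is_tonic_not_phasic(self):
        values = np.ones(2000)
        values[100:100 + int(6 * RATE)] = 10.0  # 6 s > 5 s maximum
        assert detect_bursts(_env(values), background=1.0) == []

    def test_burst_timing_and_peak_ratio(self):
        values = np.ones(2000)
        values[640:768] = 8.0  # 1 s at 8x starting at 5 s
        (b,) = detect_bursts(_env(values), background=1.0)
        assert b.onset == pytest.approx(5.0)
        assert b.duration == pytest.approx(1.0)
        assert b.peak_ratio == pytest.approx(8.0)

    def test_threshold_is_inclusive_at_exactly_four_times(self):
        values = np.ones(1000)
        values[200:240] = 4.0  # exactly the 4x threshold, 0.3 s
        assert len(detect_bursts(_env(values), background=1.0)) == 1

    def test_matches_brute_force_run_enumeration(self):
        """Exhaustive sample-scan oracle on random envelopes <= 1000 samples."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = rng.integers(50, 1000)
            values = rng.rayleigh(1.0, n)
            values[rng.random(n) < 0.05] *= 8.0
            env = _env(values)
            got = detect_bursts(env, background=1.0)
            exp = _oracle_bursts(values, env.step, 1.0, 0.1, 5.0, 4.0)
            assert [(b.onset, b.duration) for b in got] == exp


def _oracle_bursts(values, step, bg, min_dur, max_dur, ratio):
    runs, start = [], None
    for i, v in enumerate(list(values) + [-np.inf]):
        if v >= ratio * bg and start is None:
            start = i
        elif v < ratio * bg and start is not None:
            dur = (i - start) * step
            if min_dur <= dur <= max_dur:
                runs.append((start * step, dur))
            start = None
    return runs


class TestMiniEpochs:
    def test_majority_occupancy_is_active(self):
        scores = score_mini_epochs([Burst(0.7, 1.6, 6.0)], night_len_s=30.0)
        assert scores[0].occupancy == pytest.approx(1.6 / 3.0)
        assert scores[0].active

    def test_exact_half_occupancy_is_not_active(self):
        scores = score_mini_epochs([Burst(0.0, 1.5, 6.0)], night_len_s=30.0)
        assert scores[0].occupancy == pytest.approx(0.5)
        assert not scores[0].active

    def test_no_bursts_all_inactive(self):
        scores = score_mini_epochs([], night_len_s=60.0)
        assert len(scores) == 20 and not any(s.active for s in scores)

    def test_burst_split_across_two_windows(self):
        scores = score_mini_epochs([Burst(2.0, 3.0, 6.0)], night_len_s=30.0)
        assert scores[0].occupancy == pytest.approx(1.0 / 3.0)
        assert scores[1].occupancy == pytest.approx(2.0 / 3.0)
        assert [s.active for s in scores[:2]] == [False, True]

    def test_mini_len_must_divide_epoch(self):
        with pytest.raises(ValueError, match="divide"):
            score_mini_epochs([], night_len_s=30.0, mini_len=4.0)

    def test_burst_outside_night_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            score_mini_epochs([Burst(29.5, 2.0, 6.0)], night_len_s=30.0)


def _mini_scores(active_windows, n_mini):
    return score_mini_epochs(
        [Burst(w * 3.0 + 0.2, 2.0, 6.0) for w in active_windows],
        night_len_s=n_mini * 3.0,
    )


class TestEpochScoring:
    def test_no_activity_scores_zero_percent(self):
        h = Hypnogram(np.array(["REM"] * 100, dtype=object))
        res = score_epochs(_mini_scores([], 1000), h)
        assert res.rwa_pct == 0.0 and not res.no_rem

    def test_counting_rule(self):
        h = Hypnogram(np.array(["REM"] * 100, dtype=object))
        active = [e * 10 for e in range(12)]  # first mini of 12 epochs
        res = score_epochs(_mini_scores(active, 1000), h)
        assert res.rwa_pct == pytest.approx(12.0)
        assert res.rem_epoch_flags.sum() == 12

    def test_non_rem_activity_is_ignored(self):
        h = Hypnogram(np.array(["N2"] * 50 + ["REM"] * 50, dtype=object))
        active = list(range(0, 500, 10))  # every N2 epoch active, REM silent
        res = score_epochs(_mini_scores(active, 1000), h)
        assert res.rwa_pct == 0.0

    def test_no_rem_night_is_explicit_not_zero(self):
        h = Hypnogram(np.array(["N2"] * 100, dtype=object))
        res = score_epochs(_mini_scores([], 1000), h)
        assert res.no_rem and math.isnan(res.rwa_pct)

    def test_k_of_ten_rule_configurable(self):
        h = Hypnogram(np.array(["REM"] * 10, dtype=object))
        mini = _mini_scores([0, 1], 100)  # 2 active minis in epoch 0
        assert score_epochs(mini, h, min_active=2).rwa_pct == pytest.approx(10.0)
        assert score_epochs(mini, h, min_active=3).rwa_pct == 0.0


class TestPatientClassification:
    def test_silent_nights_are_negative(self):
        res = _status([0.0, 0.0])
        assert not res.rwa_positive and res.aggregate_pct == 0.0

    def test_smallest_observed_positive_value_is_positive(self):
        assert _status([1.2, 1.2]).rwa_positive

    def test_mean_aggregation(self):
        assert _status([10.0, 30.0]).aggregate_pct == pytest.approx(20.0)

    def test_max_aggregation_option(self):
        res = _status([10.0, 30.0], aggregation="max")
        assert res.aggregate_pct == 30.0

    def test_all_nights_without_rem_error(self):
        h = Hypnogram(np.array(["N2"] * 10, dtype=object))
        night = score_epochs(_mini_scores([], 100), h)
        with pytest.raises(ValueError, match="no night"):
            classify_patient([night, night])


def _status(pcts, **kw):
    h = Hypnogram(np.array(["REM"] * 100, dtype=object))
    nights = []
    for pct in pcts:
        active = [e * 10 for e in range(int(round(pct)))]
        nights.append(score_epochs(_mini_scores(active, 1000), h))
    return classify_patient(nights, **kw)


class TestEndToEnd:
    def test_scale_invariance_of_full_chain(self, short_cfg):
        """Multiplying the raw chin signal by c > 0 changes nothing scored."""
        from rwahome.pipeline import simulate_and_score_night
        from rwahome.synth import generate_hypnogram, make_burst_plan, synthesize_recording

        sim = short_cfg.simulation_config(seed=4)
        hyp = generate_hypnogram(sim)
        plan = make_burst_plan(hyp, 25.0)
        rec = synthesize_recording(hyp, plan, sim)
        base = score_recording(rec.chin, sim.sampling_rate, hyp)
        for c in (0.001, 37.0):
            scaled = score_recording(c * rec.chin, sim.sampling_rate, hyp)
            assert scaled.rwa_pct == base.rwa_pct
            assert np.array_equal(scaled.rem_epoch_flags, base.rem_epoch_flags)
            assert len(scaled.bursts) == len(base.bursts)

    def test_adding_a_burst_is_monotone(self):
        """An extra burst never lowers occupancy, flags, or RWA%."""
        h = Hypnogram(np.array(["REM"] * 20, dtype=object))
        night_len = 600.0
        base_bursts = [Burst(i * 30.0 + 0.2, 2.0, 6.0) for i in range(0, 20, 4)]
        base = score_epochs(score_mini_epochs(base_bursts, night_len), h, bursts=base_bursts)
        extra = base_bursts + [Burst(7 * 30.0 + 10.0, 2.5, 6.0)]
        more = score_epochs(score_mini_epochs(extra, night_len), h, bursts=extra)
        assert more.rwa_pct >= base.rwa_pct
        assert np.all(more.rem_epoch_flags >= base.rem_epoch_flags)
        occ_base = np.array([m.occupancy for m in base.mini_scores])
        occ_more = np.array([m.occupancy for m in more.mini_scores])
        assert np.all(occ_more >= occ_base - 1e-12)
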