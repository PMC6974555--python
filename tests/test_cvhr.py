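"""CVHR scoring: arousal detection, episode assembly, SDB classification."""

import numpy as np
import pytest

from cvhrisk.cvhr import (
    Arousal,
    FlatTachogramError,
    assemble_episodes,
    classify_sdb,
    detect_arousals,
    quantify_cvhr,
    score_cvhr,
)
from cvhrisk.rr_io import nn_filter
from cvhrisk.synthetic_data import EpisodeSpec, TachogramSpec, simulate_tachogram
from cvhrisk.tachogram import Tachogram, build_tachogram, classify_flat


def plateau_tachogram(spans, base=60.0, duration_s=1200.0, dt=0.5):
    """Evenly sampled tachogram with rectangular HR plateaus (start, dur, delta)."""
    t = np.arange(0.0, duration_s, dt)
    hr = np.full_like(t, base)
    for start, dur, delta in spans:
        hr[(t >= start) & (t < start + dur)] += delta
    return Tachogram(times=t, hr_bpm=hr, hr_smooth_bpm=hr.copy(), rsa_amplitude_bpm=0.0)


def arousal(start, dur=15.0, delta=8.0):
    return Arousal(start_s=start, end_s=start + dur, delta_bpm=delta)


class TestDetectArousals:
    def test_plateau_meeting_both_thresholds(self):
        tach = plateau_tachogram([(600, 15, 8.0)])
        found = detect_arousals(tach)
        assert len(found) == 1
        a = found[0]
        assert a.delta_bpm == pytest.approx(8.0, abs=0.5)
        assert a.duration_s == pytest.approx(15.0, abs=1.5)

    def test_short_plateau_rejected_by_duration_rule(self):
        tach = plateau_tachogram([(600, 8, 8.0)])
        assert detect_arousals(tach) == []

    def test_low_plateau_rejected_by_amplitude_rule(self):
        tach = plateau_tachogram([(600, 30, 5.0)])
        assert detect_arousals(tach) == []

    def test_two_separated_surges_detected_separately(self):
        tach = plateau_tachogram([(400, 15, 10.0), (475, 15, 10.0)])
        found = detect_arousals(tach)
        assert len(found) == 2
        assert found[0].end_s < found[1].start_s

    def test_flat_input_routed_to_indeterminate(self):
        tach = plateau_tachogram([])
        flat = classify_flat(tach)
        assert flat.is_flat
        with pytest.raises(FlatTachogramError):
            detect_arousals(tach, flat)

    def test_every_reported_arousal_satisfies_stored_thresholds(self):
        spec = TachogramSpec(
            duration_s=7200,
            episodes=(EpisodeSpec(start_s=600, n_cycles=6), EpisodeSpec(start_s=2000, n_cycles=4)),
            seed=5,
        )
        series, _ = simulate_tachogram(spec)
        found = detect_arousals(build_tachogram(nn_filter(series)))
        assert found, "planted surges must be found"
        for a in found:
            assert a.delta_bpm >= 6.0
            assert a.duration_s >= 10.0


def brute_force_episodes(arousals, max_gap=120.0, min_len=3):
    """Enumerate all maximal chains of successively-close arousals."""
    arousals = sorted(arousals, key=lambda a: a.start_s)
    chains = []
    i = 0
    while i < len(arousals):
        j = i
        while (
            j + 1 < len(arousals)
            and arousals[j + 1].start_s - arousals[j].end_s <= max_gap
        ):
            j += 1
        chains.append(arousals[i : j + 1])
        i = j + 1
    return [
        (c[0].start_s, c[-1].end_s, len(c)) for c in chains if len(c) >= min_len
    ]


class TestAssembleEpisodes:
    def test_three_arousals_one_minute_apart(self):
        eps = assemble_episodes([arousal(0), arousal(60), arousal(120)])
        assert len(eps) == 1
        ep = eps[0]
        assert (ep.start_s, ep.end_s, ep.n_arousals) == (0, 135, 3)
        assert ep.duration_min == pytest.approx(2.25)

    def test_two_arousals_never_form_an_episode(self):
        assert assemble_episodes([arousal(0), arousal(30)]) == []

    def test_long_gap_splits_into_two_short_chains(self):
        eps = assemble_episodes([arousal(0), arousal(60), arousal(300), arousal(360)])
        assert eps == []

    def test_six_arousals_single_chain(self):
        eps = assemble_episodes([arousal(90 * k) for k in range(6)])
        assert len(eps) == 1
        assert eps[0].n_arousals == 6

    def test_agrees_with_brute_force_chaining(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(0, 40))
            starts = np.cumsum(rng.uniform(20, 200, size=n))
            arousals = [arousal(float(s), dur=12.0) for s in starts]
            got = [(e.start_s, e.end_s, e.n_arousals) for e in assemble_episodes(arousals)]
            assert got == brute_force_episodes(arousals)


class TestQuantifyCVHR:
    def test_empty_is_zero(self):
        assert quantify_cvhr([]) == 0.0

    def test_durations_sum(self):
        eps = assemble_episodes(
            [arousal(0), arousal(60), arousal(120)]
            + [arousal(1000 + 90 * k) for k in range(4)]
        )
        # spans: 135 s and 285 s -> 2.25 + 4.75 min
        assert quantify_cvhr(eps) == pytest.approx(2.25 + 4.75)

    def test_overlap_is_an_internal_error(self):
        e1 = assemble_episodes([arousal(0), arousal(60), arousal(120)])[0]
        e2 = assemble_episodes([arousal(100), arousal(160), arousal(220)])[0]
        with pytest.raises(ValueError, match="overlap"):
            quantify_cvhr([e1, e2])


class TestClassifySDB:
    @pytest.mark.parametrize(
        "minutes, flat, expected",
        [
            (72.0, False, "present"),
            (71.9, False, "absent"),
            (200.0, True, "indeterminate_flat"),
            (0.0, False, "absent"),
        ],
    )
    def test_cutpoint_and_flat_routing(self, minutes, flat, expected):
        assert classify_sdb(minutes, flat, segment_min=360.0) == expected

    def test_cutoff_scales_with_segment(self):
        assert classify_sdb(24.0, False, segment_min=120.0) == "present"
        assert classify_sdb(23.9, False, segment_min=120.0) == "absent"

    def test_minutes_exceeding_segment_rejected(self):
        with pytest.raises(ValueError):
            classify_sdb(400.0, False, segment_min=360.0)


class TestEndToEnd:
    def test_time_translation_invariance(self):
        spec = TachogramSpec(
            duration_s=7200, episodes=(EpisodeSpec(start_s=1000, n_cycles=5),), seed=9
        )
        series, _ = simulate_tachogram(spec)
        tach = build_tachogram(nn_filter(series))
        shifted = Tachogram(
            times=tach.times + 3000.0,
            hr_bpm=tach.hr_bpm,
            hr_smooth_bpm=tach.hr_smooth_bpm,
            rsa_amplitude_bpm=tach.rsa_amplitude_bpm,
        )
        m1 = quantify_cvhr(assemble_episodes(detect_arousals(tach)))
        m2 = quantify_cvhr(assemble_episodes(detect_arousals(shifted)))
        assert m2 == pytest.approx(m1, abs=0.05)

    def test_planted_episodes_recovered_small_batch(self):
        hits, total = 0, 0
        for seed in range(5):
            spec = TachogramSpec(
                duration_s=7200,
                episodes=(
                    EpisodeSpec(start_s=500, n_cycles=4),
                    EpisodeSpec(start_s=2500, n_cycles=5),
                    EpisodeSpec(start_s=5000, n_cycles=3),
                ),
                noise_sd_bpm=0.5,
                seed=seed,
            )
            series, truth = simulate_tachogram(spec)
            tach = build_tachogram(nn_filter(series))
            res = score_cvhr(tach, classify_flat(tach), segment_min=120.0)
            total += truth.n_episodes
            for ts, te in truth.episode_intervals:
                hits += any(
                    abs(e.start_s - ts) < 30 and abs(e.end_s - te) < 30 for e in res.episodes
                )
            assert abs(res.cvhr_minutes - truth.cvhr_minutes) <= 0.1 * truth.cvhr_minutes
        assert hits == total
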