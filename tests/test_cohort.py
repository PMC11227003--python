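import numpy as np
import pandas as pd
import pytest

from agiwear import cohort as coh
from agiwear.streams import extract_window


class TestPromptSchedule:
    def test_legality_over_many_seeds(self):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            s = coh.generate_prompt_schedule(rng)
            assert s.size == 9
            assert np.all(np.diff(np.sort(s)) >= 3000.0)  # >= 50 min apart
            assert s.min() >= coh.PROMPT_START_S
            assert s.max() <= coh.PROMPT_END_S

    def test_same_seed_state_identical(self):
        a = coh.generate_prompt_schedule(np.random.default_rng(3))
        b = coh.generate_prompt_schedule(np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestEpisodes:
    def test_zero_rate_gives_no_episodes(self):
        cfg = coh.SimConfig(n_patients=1, days_per_patient=1,
                            episode_base_rate=0.0, eda_hz=8.0)
        rng = np.random.default_rng(0)
        assert coh.simulate_episodes(cfg, rng, "P01", 0) == []

    def test_block_counts_ordered_by_sundowning_multiplier(self):
        cfg = coh.SimConfig(n_patients=1, days_per_patient=1,
                            sundowning_multipliers=(0.5, 1.0, 1.5, 2.0),
                            eda_hz=8.0)
        rng = np.random.default_rng(1)
        counts = np.zeros(4)
        for day in range(3000):
            for ep in coh.simulate_episodes(cfg, rng, "P01", 0):
                h = (ep.start % coh.DAY_S) / 3600.0
                counts[coh._block_of_hour(h)] += 1
        assert np.all(np.diff(counts) > 0)

    def test_median_duration_near_six_minutes(self):
        cfg = coh.SimConfig(n_patients=1, days_per_patient=1, eda_hz=8.0)
        rng = np.random.default_rng(2)
        durations = []
        while len(durations) < 10_000:
            for ep in coh.simulate_episodes(cfg, rng, "P01", 0):
                durations.append(ep.end - ep.start)
        med = np.median(durations)
        assert med == pytest.approx(360.0, rel=0.10)

    def test_non_overlapping_per_patient(self):
        cfg = coh.SimConfig(n_patients=1, days_per_patient=1,
                            episode_base_rate=5.0, eda_hz=8.0)
        rng = np.random.default_rng(3)
        eps = coh.simulate_episodes(cfg, rng, "P01", 0)
        for a, b in zip(eps, eps[1:]):
            assert b.start >= a.end


class TestSurveys:
    def _day(self, cfg, seed=0):
        seeds = coh.day_seedseqs(cfg)
        return coh.generate_patient_day(cfg, "P01", 0, seeds[("P01", 0)])

    def test_spontaneous_rate_zero_gives_nine_per_day(self):
        cfg = coh.SimConfig(n_patients=1, days_per_patient=1,
                            spontaneous_rate=0.0, eda_hz=8.0)
        _, _, surveys = self._day(cfg)
        assert len(surveys) == 9
        assert surveys["prompted"].all()

    def test_prompt_inside_motor_episode_scores_motor_item(self):
        rng = np.random.default_rng(0)
        eps = [coh.EpisodeTruth("P01", 40000.0, 41000.0, "motor")]
        schedule = np.array([40500.0])
        s = coh.emit_surveys(eps, schedule, 0.0, rng, "P01", 0)
        assert s.iloc[0]["pas_motor"] > 0
        assert s.iloc[0]["pas_vocal"] == 0

    def test_prompt_outside_episodes_scores_zero(self):
        rng = np.random.default_rng(0)
        s = coh.emit_surveys([], np.array([40500.0]), 0.0, rng, "P01", 0)
        assert s.iloc[0][["pas_vocal", "pas_motor", "pas_aggr",
                          "pas_resist"]].sum() == 0


class TestStreams:
    def test_planted_hr_delta_recovered(self):
        eff = coh.EffectProfile(delta_hr=10.0, motor_movement_scale=1.0,
                                verbal_movement_scale=1.0, verbal_eda_scale=1.0)
        cfg = coh.SimConfig(n_patients=1, days_per_patient=1, eda_hz=8.0,
                            effect_profile=eff,
                            missingness=coh.MissingnessConfig(
                                hr_missing_prob=0.0, nonwear_prob=0.0))
        rng = np.random.default_rng(0)
        diffs = []
        for day in range(30):
            eps = coh.simulate_episodes(cfg, rng, "P01", 0)
            # ACC is irrelevant here; skip materializing it for speed
            streams = coh.synthesize_streams(cfg, eps, "P01", 0, rng,
                                             acc_windows_only=True)
            hr = streams["hr"]
            t = hr.times()
            in_ep = np.zeros(t.size, dtype=bool)
            for ep in eps:
                # interior of episodes (edges are smoothed)
                in_ep |= (t >= ep.start + 30) & (t < ep.end - 30)
            if in_ep.sum() > 50 and (~in_ep).sum() > 50:
                diffs.append(np.nanmean(hr.values[in_ep])
                             - np.nanmean(hr.values[~in_ep]))
        assert np.mean(diffs) == pytest.approx(10.0, abs=1.5)

    def test_null_effect_profile_gives_stationary_baselines(self):
        eff = coh.EffectProfile(delta_tonic_level=0, delta_phasic_rate=0,
                                delta_hr=0, delta_st=0, delta_acc_sd=0)
        cfg = coh.SimConfig(n_patients=1, days_per_patient=1, eda_hz=8.0,
                            effect_profile=eff)
        rng = np.random.default_rng(0)
        eps = coh.simulate_episodes(cfg, rng, "P01", 0)
        streams = coh.synthesize_streams(cfg, eps, "P01", 0, rng,
                                         acc_windows_only=True)
        hr = streams["hr"].values
        t = streams["hr"].times()
        in_ep = np.zeros(t.size, dtype=bool)
        for ep in eps:
            in_ep |= (t >= ep.start) & (t < ep.end)
        if in_ep.any() and (~in_ep).any():
            assert abs(np.nanmean(hr[in_ep]) - np.nanmean(hr[~in_ep])) < 3.0

    def test_nonwear_probability_one_empties_all_survey_windows(self):
        cfg = coh.SimConfig(n_patients=1, days_per_patient=1, eda_hz=8.0,
                            missingness=coh.MissingnessConfig(nonwear_prob=1.0))
        seeds = coh.day_seedseqs(cfg)
        streams, _, surveys = coh.generate_patient_day(cfg, "P01", 0,
                                                       seeds[("P01", 0)])
        for t in surveys["timestamp_s"]:
            for mod in ("acc", "hr", "eda", "st"):
                w = extract_window(streams[mod], t)
                assert w.n_present() == 0

    def test_eda_device_rate_emission(self):
        cfg = coh.SimConfig(n_patients=1, days_per_patient=1, eda_hz=256.0)
        rng = np.random.default_rng(0)
        streams = coh.synthesize_streams(cfg, [], "P01", 0, rng,
                                         acc_windows_only=True)
        assert streams["eda"].sampling_rate == 256.0
        # ADC quantization: all values on the 1/128 uS grid
        v = streams["eda"].values[:1000]
        assert np.allclose(v * 128, np.round(v * 128), atol=1e-9)


class TestDeterminism:
    def test_same_config_same_cohort(self):
        cfg = coh.SimConfig(n_patients=2, days_per_patient=1, seed=9,
                            eda_hz=8.0)
        a = coh.generate_cohort(cfg)
        b = coh.generate_cohort(cfg)
        assert a.surveys.equals(b.surveys)
        assert a.episodes.equals(b.episodes)
        for key in a.streams:
            assert np.array_equal(a.streams[key].values,
                                  b.streams[key].values, equal_nan=True)

    def test_roundtrip_through_disk(self, tmp_path, tiny_cohort):
        from dataclasses import replace as dc_replace

        # truncate streams so the text round-trip stays fast; the I/O layer
        # is oblivious to stream length
        trimmed = coh.Cohort(
            config=tiny_cohort.config,
            streams={k: dc_replace(s, values=s.values[:2000])
                     for k, s in tiny_cohort.streams.items()},
            surveys=tiny_cohort.surveys, episodes=tiny_cohort.episodes)
        coh.write_cohort(trimmed, tmp_path / "cohort")
        back = coh.read_cohort(tmp_path / "cohort")
        assert back.config == trimmed.config
        assert set(back.streams) == set(trimmed.streams)
        key = ("P01", 0, "hr")
        assert np.allclose(back.streams[key].values,
                           trimmed.streams[key].values,
                           equal_nan=True, atol=1e-5)
        assert len(back.surveys) == len(trimmed.surveys)
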