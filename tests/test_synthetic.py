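"""Generator: LOP sampling, scene rendering, dataset bookkeeping."""

import numpy as np
import pytest
from scipy import stats as sps

from stunflow.errors import ConfigurationError, ParameterError
from stunflow.synthetic import (
    ScenarioConfig,
    generate_dataset,
    generate_scenario,
    sample_lop_times,
    simulate_gondola,
)


class TestSampleLopTimes:
    def test_zero_sd_is_point_mass(self):
        assert (sample_lop_times(5, lop_mean=13.4, lop_sd=0.0, seed=3) == 13.4).all()

    def test_support_is_strictly_positive(self):
        t = sample_lop_times(10_000, 13.4, 3.8, seed=0)
        assert (t > 0).all()

    def test_moments_recovered(self):
        t = sample_lop_times(20_000, 13.4, 3.8, seed=1)
        assert t.mean() == pytest.approx(13.4, abs=0.1)
        assert t.std(ddof=1) == pytest.approx(3.8, abs=0.1)

    def test_deterministic_given_seed(self):
        a = sample_lop_times(50, 13.4, 3.8, seed=7)
        b = sample_lop_times(50, 13.4, 3.8, seed=7)
        assert (a == b).all()

    @pytest.mark.parametrize("kwargs", [dict(n=0), dict(n=5, lop_mean=0.0), dict(n=5, lop_sd=-1.0)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            sample_lop_times(**{"lop_mean": 13.4, "lop_sd": 3.8, **kwargs})

    def test_lognormal_family_matches_moments(self):
        t = sample_lop_times(50_000, 13.4, 3.8, seed=2, family="lognormal")
        assert t.mean() == pytest.approx(13.4, rel=0.02)
        assert t.std(ddof=1) == pytest.approx(3.8, rel=0.05)


class TestGenerateScenario:
    def test_static_scene_has_identical_frames_and_zero_flow(self):
        cfg = ScenarioConfig(
            group_size=2, base_speed=0, response_speed=0, excitation_speed=0, seed=5
        )
        frames, truth = generate_scenario(cfg)
        assert (frames == frames[0]).all()
        assert (truth.true_flow == 0).all()
        assert (truth.displacements == 0).all()

    def test_deterministic_given_seed(self):
        cfg = ScenarioConfig(group_size=3, seed=9)
        f1, t1 = generate_scenario(cfg)
        f2, t2 = generate_scenario(cfg)
        assert (f1 == f2).all()
        assert (t1.masks == t2.masks).all()
        assert (t1.lop_times == t2.lop_times).all()

    def test_mask_equals_rendered_foreground(self, small_scene):
        _, sample = small_scene
        assert ((sample.frames > 0) == sample.truth.masks).all()

    def test_flow_zero_outside_masks(self, small_scene):
        _, sample = small_scene
        off = ~sample.truth.masks[1:]
        assert (sample.truth.true_flow[:, 0][off] == 0).all()
        assert (sample.truth.true_flow[:, 1][off] == 0).all()

    def test_flop_llop_are_min_max_of_lop_times(self, small_scene):
        _, sample = small_scene
        truth = sample.truth
        assert truth.flop_frame == truth.lop_frames.min()
        assert truth.llop_frame == truth.lop_frames.max()
        assert truth.flop_time <= truth.llop_time

    def test_pigs_never_overlap(self, small_scene):
        _, sample = small_scene
        # mask area is constant = group_size * single-pig area
        areas = sample.truth.masks.sum(axis=(1, 2))
        assert (areas == 3 * sample.truth.pig_area).all()

    def test_arena_too_small_raises(self):
        with pytest.raises(ConfigurationError):
            generate_scenario(ScenarioConfig(group_size=9, arena_width=40, arena_height=40))


class TestKinematicMode:
    def test_deterministic_and_exchangeable_event_structure(self):
        s1 = simulate_gondola(ScenarioConfig(group_size=4, seed=3), render=False)
        s2 = simulate_gondola(ScenarioConfig(group_size=4, seed=3), render=False)
        assert (s1.truth.displacements == s2.truth.displacements).all()

    def test_activity_phases(self):
        cfg = ScenarioConfig(
            group_size=2, base_speed=0, response_speed=4, excitation_speed=0, seed=1
        )
        s = simulate_gondola(cfg, render=False)
        series = s.truth.activity_series()
        fr, flop = s.truth.t_first_response, s.truth.flop_frame
        pre = series.window(1, fr)
        induction = series.window(fr, flop)
        assert (pre == 0).all()
        # integer rounding keeps realized speeds near the 4 px/frame target
        assert induction.mean() == pytest.approx(4.0, abs=0.4)
        post = series.window(s.truth.llop_frame, len(series) + 1)
        assert (post == 0).all()


class TestGenerateDataset:
    def test_study_bookkeeping(self):
        samples = generate_dataset({3: 10, 4: 57, 7: 59, 8: 77}, mode="events", seed=0)
        assert len(samples) == 203
        assert sum(s.group_size for s in samples) == 1287

    def test_single_gondola(self):
        samples = generate_dataset({3: 1}, mode="events", seed=1)
        assert len(samples) == 1 and samples[0].group_size == 3

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            generate_dataset({3: -1}, mode="events")

    def test_density_shift_raises_mean_llop(self):
        # common seeds, >=100 replicate gondolas per arm
        shifted, null = [], []
        for seed in range(100):
            a = generate_dataset({7: 1}, mode="events", seed=seed)[0]
            b = generate_dataset(
                {7: 1}, mode="events", seed=seed,
                group_overrides={7: {"density_lop_shift": 4.0}},
            )[0]
            null.append(a.truth.llop_time)
            shifted.append(b.truth.llop_time)
        assert np.mean(shifted) > np.mean(null)

    def test_null_exchangeability_across_group_sizes(self):
        # under the null model, per-pig LOP times from 3-pig and 8-pig
        # gondolas are draws from one distribution: KS should not reject
        # at alpha=0.05 in >= 95% of replicates
        not_rejected = 0
        reps = 100
        for seed in range(reps):
            samples = generate_dataset({3: 40, 8: 15}, mode="events", seed=seed)
            small = np.concatenate(
                [s.truth.lop_times for s in samples if s.group_size == 3]
            )
            large = np.concatenate(
                [s.truth.lop_times for s in samples if s.group_size == 8]
            )
            not_rejected += sps.ks_2samp(small, large).pvalue >= 0.05
        assert not_rejected >= 0.95 * reps
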