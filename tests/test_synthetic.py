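"""Generator contracts: determinism, bounds, design arithmetic, effect
injection and the recognition-task link."""

import numpy as np
import pytest

from facekin import (
    EffectSpec,
    ErLinkParams,
    SimulationConfig,
    generate_dataset,
    generate_er_ratings,
    generate_feature_table,
    generate_participants,
    generate_recording,
)
from facekin.blendshapes import GROUPS, N_BLENDSHAPES
from facekin.types import ConfigurationError


class TestParticipants:
    def test_counts_per_group(self):
        config = SimulationConfig(n_per_group=25, seed=1)
        participants = generate_participants(config)
        assert len(participants) == 50
        for group in GROUPS:
            assert sum(p.group == group for p in participants) == 25

    def test_asymmetric_group_sizes(self):
        config = SimulationConfig(group_sizes=(25, 26), seed=1)
        participants = generate_participants(config)
        assert sum(p.group == "autistic" for p in participants) == 25
        assert sum(p.group == "non_autistic" for p in participants) == 26

    def test_trait_means_match_configured_defaults_at_large_n(self):
        config = SimulationConfig(n_per_group=5000, seed=2)
        participants = generate_participants(config)
        tas = {g: np.mean([p.tas for p in participants if p.group == g])
               for g in GROUPS}
        assert tas["non_autistic"] == pytest.approx(43.12, abs=0.5)
        assert tas["autistic"] == pytest.approx(62.24, abs=0.5)

    def test_instrument_ranges_enforced(self):
        config = SimulationConfig(n_per_group=500, seed=3)
        for p in generate_participants(config):
            assert 20 <= p.tas <= 100
            assert 0 <= p.aq <= 50
            assert 70 <= p.iq <= 160

    def test_deterministic_under_seed(self):
        config = SimulationConfig(n_per_group=10, seed=4)
        assert generate_participants(config) == generate_participants(config)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_per_group=0)


class TestRecordings:
    def test_cued_frame_count_and_bounds(self, small_dataset):
        rec = small_dataset.get_recording("A001", "cued", "anger", 1)
        assert rec.n_frames == small_dataset.config.frames_cued
        assert rec.blendshapes.shape[1] == N_BLENDSHAPES
        assert rec.blendshapes.min() >= 0 and rec.blendshapes.max() <= 1

    def test_spoken_length_within_jitter_bounds(self, small_dataset):
        config = small_dataset.config
        lengths = {small_dataset.get_recording("N001", "spoken", e, r).n_frames
                   for e in config.emotions
                   for r in range(1, config.n_repetitions + 1)}
        lo = config.frames_spoken_mean - config.frames_spoken_jitter
        hi = config.frames_spoken_mean + config.frames_spoken_jitter
        assert all(lo <= n <= hi for n in lengths)

    def test_bounds_hold_under_extreme_effects(self):
        effect = EffectSpec(measure="activation", unit_ids=(0, 5, 10),
                            time_window=(1, 30), emotion="anger",
                            condition="cued", group_effect=5.0,
                            tas_slope=0.5)
        config = SimulationConfig(n_per_group=2, n_repetitions=2,
                                  frames_cued=40, frames_spoken_mean=30,
                                  frames_spoken_jitter=0, residual_sd=0.3,
                                  effects=(effect,), seed=6)
        for rec in generate_dataset(config).iter_recordings():
            assert rec.blendshapes.min() >= 0
            assert rec.blendshapes.max() <= 1

    def test_zero_noise_repetitions_identical(self, zero_noise_dataset):
        a = zero_noise_dataset.get_recording("A001", "cued", "anger", 1)
        b = zero_noise_dataset.get_recording("A001", "cued", "anger", 3)
        np.testing.assert_array_equal(a.blendshapes, b.blendshapes)
        np.testing.assert_array_equal(a.landmarks, b.landmarks)

    def test_bit_identical_datasets_under_same_seed(self, small_config):
        d1 = generate_dataset(small_config)
        d2 = generate_dataset(small_config)
        assert d1.manifest.equals(d2.manifest)
        r1 = d1.get_recording("A003", "spoken", "sadness", 2)
        r2 = d2.get_recording("A003", "spoken", "sadness", 2)
        np.testing.assert_array_equal(r1.blendshapes, r2.blendshapes)
        np.testing.assert_array_equal(r1.landmarks, r2.landmarks)

    def test_different_seed_differs(self, small_config, small_dataset):
        other = generate_dataset(
            SimulationConfig(**{**vars(small_config), "seed": 999}))
        r1 = small_dataset.get_recording("A001", "cued", "anger", 1)
        r2 = other.get_recording("A001", "cued", "anger", 1)
        assert not np.array_equal(r1.blendshapes, r2.blendshapes)

    def test_unknown_condition_rejected(self, small_config):
        participants = generate_participants(small_config)
        with pytest.raises(ConfigurationError):
            generate_recording(participants[0], "whistled", "anger", 1,
                               small_config)


class TestEffectInjection:
    def test_group_contrast_converges_to_injected_effect(self):
        """Monte-Carlo mean contrast at the targeted unit/window ~ +0.3."""
        effect = EffectSpec(measure="activation", unit_ids=(10,),
                            time_window=(180, 360), emotion="anger",
                            condition="cued", group_effect=0.3)
        config = SimulationConfig(n_per_group=50, n_repetitions=4,
                                  frames_cued=540, conditions=("cued",),
                                  emotions=("anger",), effects=(effect,),
                                  seed=7)
        dataset = generate_dataset(config)
        window_means = {g: [] for g in GROUPS}
        for rec in dataset.iter_recordings():
            group = dataset.participant_map[rec.participant_id].group
            window_means[group].append(rec.blendshapes[179:360, 10].mean())
        # contrast over >= 200 recordings per group, tolerance 3 SE of the
        # participant-level means (subject intercepts are shared within
        # participant, so the SE uses participant counts)
        contrast = (np.mean(window_means["autistic"])
                    - np.mean(window_means["non_autistic"]))
        se = np.sqrt(2) * config.subject_sd / np.sqrt(config.n_per_group)
        assert len(window_means["autistic"]) == 200
        assert contrast == pytest.approx(0.3, abs=3 * se)

    def test_null_config_contrast_centred_at_zero(self, small_dataset):
        config = small_dataset.config
        means = {g: [] for g in GROUPS}
        for rec in small_dataset.iter_recordings(condition="cued",
                                                 emotion="anger"):
            group = small_dataset.participant_map[rec.participant_id].group
            means[group].append(rec.blendshapes.mean(axis=0))
        contrast = (np.mean(means["autistic"], axis=0)
                    - np.mean(means["non_autistic"], axis=0))
        se = np.sqrt(2) * config.subject_sd / np.sqrt(config.n_per_group)
        assert np.abs(contrast).max() < 4 * se

    def test_effect_window_outside_recording_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(frames_cued=50, effects=(EffectSpec(
                measure="activation", unit_ids=(0,), time_window=(1, 400),
                emotion="anger", condition="cued", group_effect=0.1),))


class TestDesignArithmetic:
    def test_small_design_product(self):
        config = SimulationConfig(n_per_group=1, n_repetitions=2,
                                  emotions=("anger",), seed=8)
        dataset = generate_dataset(config)
        for condition in ("cued", "spoken"):
            sub = dataset.manifest[dataset.manifest.condition == condition]
            assert len(sub) == 4  # 2 participants x 1 emotion x 2 reps

    def test_manifest_rows_equal_emitted_recordings(self, small_dataset):
        n = sum(1 for _ in small_dataset.iter_recordings())
        assert n == len(small_dataset.manifest) == small_dataset.n_recordings


class TestErRatings:
    def test_trial_count_and_rating_bounds(self, small_dataset):
        ratings = generate_er_ratings(small_dataset.participants,
                                      ErLinkParams(), seed=9)
        counts = ratings.groupby("participant_id")["trial"].count()
        assert (counts == 108).all()
        values = ratings[["rating_anger", "rating_happiness",
                          "rating_sadness"]].to_numpy()
        assert values.min() >= 0 and values.max() <= 10

    def test_null_link_gives_no_correlation(self):
        config = SimulationConfig(n_per_group=60, seed=10)
        participants = generate_participants(config)
        scores = {p.participant_id: i for i, p in enumerate(participants)}
        ratings = generate_er_ratings(
            participants, ErLinkParams(slopes={g: 0.0 for g in GROUPS}),
            seed=10, scores=scores)
        from facekin import er_accuracy
        _, acc = er_accuracy(ratings)
        score_vec = np.array([scores[i] for i in acc.index])
        r = np.corrcoef(score_vec, acc.to_numpy())[0, 1]
        assert abs(r) < 0.2

    def test_positive_link_in_one_group_only(self):
        config = SimulationConfig(n_per_group=60, seed=12)
        participants = generate_participants(config)
        rng = np.random.default_rng(12)
        scores = {p.participant_id: rng.normal() for p in participants}
        ratings = generate_er_ratings(
            participants,
            ErLinkParams(slopes={"autistic": 0.0, "non_autistic": 2.0}),
            seed=12, scores=scores)
        from facekin import er_accuracy
        _, acc = er_accuracy(ratings)
        r = {}
        for g in GROUPS:
            ids = [p.participant_id for p in participants if p.group == g]
            r[g] = np.corrcoef([scores[i] for i in ids],
                               [acc[i] for i in ids])[0, 1]
        assert r["non_autistic"] > 0.6
        assert abs(r["autistic"]) < 0.35


class TestFeatureTable:
    def test_layout_and_determinism(self):
        t1 = generate_feature_table(20, seed=13)
        t2 = generate_feature_table(20, seed=13)
        assert t1.equals(t2)
        assert len(t1) == 40
        assert {"jerk_precision_spoken", "activation_mean_cued", "aq", "tas",
                "iq", "er_accuracy"} <= set(t1.columns)

    def test_link_produces_group_specific_correlation(self):
        table = generate_feature_table(
            300, seed=14, link_slopes={"autistic": 0.0, "non_autistic": 1.5})
        r = table.groupby("group").apply(
            lambda g: np.corrcoef(g["jerk_precision_spoken"],
                                  g["er_accuracy"])[0, 1],
            include_groups=False)
        assert r["non_autistic"] > 0.6
        assert abs(r["autistic"]) < 0.2
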