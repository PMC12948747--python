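"""Mixed-model fitting, engine equivalence and permutation inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from facekin import (
    EffectSpec,
    SimulationConfig,
    fit_unit_model,
    fit_units_balanced,
    generate_dataset,
    permutation_null,
    run_mass_univariate,
)
from facekin.massuni import _slice_features, _subject_level_stats, is_balanced
from facekin.types import ConfigurationError, DataError


def _simulate_crossed(rng, n_per_group=8, n_reps=4, subject_sd=0.5,
                      rep_sd=0.2, resid_sd=1.0, group_effect=0.0,
                      tas_slope=0.0):
    """Array-level simulator for the crossed random-intercept model."""
    groups, tas, subjects, reps, y = [], [], [], [], []
    u = rng.normal(0, subject_sd, 2 * n_per_group)
    v = rng.normal(0, rep_sd, n_reps)
    tas_values = rng.normal(50, 12, 2 * n_per_group)
    for s in range(2 * n_per_group):
        g = "autistic" if s < n_per_group else "non_autistic"
        for r in range(n_reps):
            groups.append(g)
            tas.append(tas_values[s])
            subjects.append(f"S{s:02d}")
            reps.append(r + 1)
            y.append((group_effect if g == "autistic" else 0.0)
                     + tas_slope * (tas_values[s] - 50)
                     + u[s] + v[r] + rng.normal(0, resid_sd))
    return (np.array(y), np.array(groups), np.array(tas),
            np.array(subjects), np.array(reps))


class TestEngineEquivalence:
    def test_balanced_collapse_matches_mixedlm(self, rng):
        """For complete balanced designs the subject-mean OLS t equals the
        REML mixed-model Wald t for the between-subject terms."""
        y, g, tas, subj, reps = _simulate_crossed(rng, group_effect=0.8)
        t_group, t_tas = fit_units_balanced(y[:, None], g, tas, subj)
        res = fit_unit_model(y, g, tas, subj, reps)
        assert res.converged
        assert res.group_stat == pytest.approx(t_group[0], abs=2e-3)
        assert res.tas_stat == pytest.approx(t_tas[0], abs=2e-3)

    def test_single_repetition_equals_ols_ancova(self, rng):
        """With one observation per subject the collapsed model IS the
        fixed-effects ANCOVA; F agrees with statsmodels OLS to 1e-6."""
        y, g, tas, subj, _ = _simulate_crossed(rng, n_reps=1, subject_sd=0.0,
                                               rep_sd=0.0, group_effect=1.0)
        t_group, t_tas = fit_units_balanced(y[:, None], g, tas, subj)
        X = sm.add_constant(pd.DataFrame({
            "group_a": (g == "autistic").astype(float),
            "tas_c": tas - tas.mean()}))
        ols = sm.OLS(y, X).fit()
        assert t_group[0] ** 2 == pytest.approx(ols.tvalues["group_a"] ** 2,
                                                abs=1e-6)
        assert t_tas[0] ** 2 == pytest.approx(ols.tvalues["tas_c"] ** 2,
                                              abs=1e-6)

    def test_sign_contract_with_zero_residual(self):
        """A pure positive group effect with no noise gives a positive
        (infinite) statistic."""
        g = np.array(["autistic"] * 6 + ["non_autistic"] * 6)
        y = (g == "autistic").astype(float) * 1.0
        tas = np.linspace(30, 70, 12)
        subj = np.array([f"S{i}" for i in range(12)])
        t_group, _ = fit_units_balanced(y[:, None], g, tas, subj)
        # residual variance is zero up to float rounding, so the statistic
        # is astronomically large; the contract under test is its sign
        assert t_group[0] > 1e6

    def test_null_statistics_are_small(self, rng):
        """Pure subject-intercept data: |t| < 2 in >= 90% of simulations."""
        small = 0
        for _ in range(100):
            y, g, tas, subj, _ = _simulate_crossed(rng, resid_sd=1.0)
            t_group, _ = fit_units_balanced(y[:, None], g, tas, subj)
            small += abs(t_group[0]) < 2
        assert small >= 90

    def test_constant_response_rejected(self):
        g = np.array(["autistic"] * 4 + ["non_autistic"] * 4)
        with pytest.raises(DataError):
            fit_unit_model(np.ones(8), g, np.arange(8), g, np.ones(8))

    def test_single_group_rejected(self, rng):
        g = np.array(["autistic"] * 8)
        y = rng.normal(size=8)
        with pytest.raises(DataError):
            fit_unit_model(y, g, np.arange(8.0),
                           np.array([f"S{i}" for i in range(8)]), np.ones(8))


class TestPermutation:
    def test_threshold_monotone_in_alpha(self, rng):
        y, g, tas, subj, _ = _simulate_crossed(rng)
        Y = np.column_stack([y, rng.normal(size=len(y))])
        thresholds = []
        for alpha in (0.01, 0.05, 0.2):
            thr, _ = permutation_null(Y, g, tas, subj, n_permutations=200,
                                      alpha=alpha, seed=5)
            thresholds.append(thr["group"])
        assert thresholds[0] >= thresholds[1] >= thresholds[2]

    def test_identity_relabelling_reproduces_observed_stats(self, rng):
        y, g, tas, subj, _ = _simulate_crossed(rng, group_effect=1.0)
        from facekin.massuni import collapse_to_subjects
        Ybar, ga, ts = collapse_to_subjects(y[:, None], g, tas, subj)
        observed = fit_units_balanced(y[:, None], g, tas, subj)
        identity = _subject_level_stats(Ybar, ga[np.arange(len(ga))], ts)
        np.testing.assert_array_equal(observed[0], identity[0])

    def test_degenerate_all_identical_stats(self):
        """When every permutation yields the same statistic the threshold
        equals that common value."""
        g = np.array(["autistic"] * 4 + ["non_autistic"] * 4)
        subj = np.array([f"S{i}" for i in range(8)])
        Y = np.zeros((8, 3))          # all stats are exactly 0
        thr, null = permutation_null(Y, g, np.arange(8.0), subj,
                                     n_permutations=100, alpha=0.05, seed=1)
        assert thr["group"] == 0.0
        assert np.all(null["group"] == 0.0)

    def test_too_few_permutations_rejected(self, rng):
        y, g, tas, subj, _ = _simulate_crossed(rng)
        with pytest.raises(ConfigurationError):
            permutation_null(y[:, None], g, tas, subj, n_permutations=50,
                             alpha=0.05, seed=1)


@pytest.fixture(scope="module")
def effect_dataset():
    effect = EffectSpec(
        measure="activation", unit_ids=(12, 30), time_window=(1, 60),
        emotion="anger", condition="cued", group_effect=0.25)
    config = SimulationConfig(
        n_per_group=10, n_repetitions=4, frames_cued=60,
        conditions=("cued",), emotions=("anger",), effects=(effect,),
        seed=21)
    return generate_dataset(config)


class TestRunMassUnivariate:
    def test_injected_effect_recovered_with_positive_sign(self,
                                                          effect_dataset):
        result = run_mass_univariate(effect_dataset, "activation", "cued",
                                     "anger", "time_averaged",
                                     n_permutations=300, seed=22)
        flagged = set(result.results.loc[
            result.results.group_significant, "unit"])
        assert flagged == {12, 30}
        stats = result.results.set_index("unit").loc[[12, 30], "group_stat"]
        assert (stats > 0).all()
        assert result.percent_significant["group"] == pytest.approx(
            100 * 2 / 44, abs=1e-9)

    def test_mixedlm_engine_agrees_with_balanced(self, effect_dataset):
        units = [12, 0]
        kwargs = dict(n_permutations=100, seed=23, units=units)
        balanced = run_mass_univariate(effect_dataset, "activation", "cued",
                                       "anger", "time_averaged",
                                       engine="balanced", **kwargs)
        mixed = run_mass_univariate(effect_dataset, "activation", "cued",
                                    "anger", "time_averaged",
                                    engine="mixedlm", **kwargs)
        np.testing.assert_allclose(balanced.results.group_stat,
                                   mixed.results.group_stat, atol=5e-3)

    def test_peak_mode_on_spoken_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError):
            run_mass_univariate(small_dataset, "activation", "spoken",
                                "anger", "peak", n_permutations=100, seed=1)

    def test_per_timepoint_family_shape(self, small_dataset):
        units = [0, 1, 2]
        result = run_mass_univariate(small_dataset, "activation", "spoken",
                                     "anger", "per_timepoint",
                                     n_permutations=100, seed=2, units=units)
        frames = small_dataset.config.frames_spoken_mean
        assert len(result.results) == len(units) * frames
        assert set(result.results.unit) == set(units)
        assert result.results.timepoint.max() == frames

    def test_jerk_measure_uses_valid_frames(self, small_dataset):
        units = [0, 1]
        result = run_mass_univariate(small_dataset, "jerk", "spoken",
                                     "anger", "per_timepoint",
                                     n_permutations=100, seed=3, units=units)
        frames = small_dataset.config.frames_spoken_mean - 4
        assert len(result.results) == len(units) * frames

    def test_balance_detection(self, small_dataset):
        Y, _, obs = _slice_features(small_dataset, "activation", "cued",
                                    "anger", "time_averaged", [0], 27)
        assert is_balanced(obs["participant_id"], obs["repetition"])
        assert not is_balanced(obs["participant_id"][:-1],
                               obs["repetition"][:-1])
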