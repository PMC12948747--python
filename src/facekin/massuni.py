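"""Mass-univariate mixed-model inference with permutation FWER control.

For every analysis unit (blendshape or landmark; optionally every unit x
timepoint), the response is modelled as a linear mixed effects model::

    y ~ 1 + group + TAS,   random intercepts for subject and repetition

where group codes the autistic (1) vs non-autistic (0) contrast and TAS is
the centred alexithymia score.  The reported per-effect statistic is the
signed square root of the Wald F for that term — i.e. sign(coefficient) *
sqrt(F), the Wald t — so its sign carries the direction of the autistic -
non-autistic contrast (or TAS slope) and its square is the F statistic.

Family-wise error is controlled by a participant-level permutation scheme:
group labels are reassigned across participants (preserving group sizes),
the models are refit, and the observed statistics are compared to the 95th
percentile of the permutation null.  By default the null pools the maximum
|statistic| across the family per permutation (max-statistic pooling,
strong FWER control); per-unit pooling is available as an option.  Because
reassigning group labels does not null the TAS slope, TAS thresholds are
obtained by permuting TAS values across participants instead.

Two fitting engines are provided.  ``"mixedlm"`` fits each unit with
statsmodels' REML MixedLM using crossed subject / repetition variance
components.  ``"balanced"`` exploits that for complete balanced designs
(every subject has every repetition exactly once) the between-subject
group and TAS tests collapse exactly to OLS on subject means: the
repetition intercept is constant across subjects and the subject-mean
regression estimates the same fixed effects with the same t statistics
(when variance estimates are interior).  The collapsed engine is vectorised
across all units and is what makes dense permutation studies tractable;
``"auto"`` selects it whenever the design is balanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .kinematics import (
    DEFAULT_PEAK_INDEX,
    peak_frame_activation,
    recording_jerk,
    resample_to_length,
)
from .synthetic import Dataset
from .types import ConfigurationError, DataError

TIMING_MODES = ("peak", "per_timepoint", "time_averaged")


@dataclass(frozen=True)
class UnitModelResult:
    """Fixed-effect statistics for one unit (and timepoint)."""

    unit_id: int
    timepoint: object              # int (1-based), "averaged" or "peak"
    group_stat: float              # sign(coef) * sqrt(F) for the group term
    tas_stat: float                # sign(coef) * sqrt(F) for the TAS term
    group_f: float
    tas_f: float
    converged: bool = True

    def __post_init__(self) -> None:
        for stat, f in ((self.group_stat, self.group_f),
                        (self.tas_stat, self.tas_f)):
            if np.isfinite(stat) and np.isfinite(f):
                assert abs(stat ** 2 - f) <= 1e-6 * max(1.0, f)


@dataclass
class MassUnivariateResult:
    """All per-unit statistics plus permutation thresholds and masks."""

    results: pd.DataFrame          # unit, timepoint, per-effect stat + flag
    thresholds: dict[str, np.ndarray | float]
    n_permutations: int
    alpha: float
    pooling: str
    measure: str
    condition: str
    emotion: str
    timing_mode: str
    null_max: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def percent_significant(self) -> dict[str, float]:
        n = len(self.results)
        return {effect: 100.0 * self.results[f"{effect}_significant"].sum() / n
                for effect in ("group", "tas")}

    def significance_mask(self, effect: str) -> np.ndarray:
        return self.results[f"{effect}_significant"].to_numpy()


# ---------------------------------------------------------------------------
# Single-unit mixed model (reference engine)

def fit_unit_model(values: np.ndarray, group: np.ndarray, tas: np.ndarray,
                   subject_ids: np.ndarray, repetition_ids: np.ndarray,
                   unit_id: int = 0, timepoint: object = "averaged",
                   ) -> UnitModelResult:
    """REML mixed model for one unit: ``y ~ group + TAS`` with crossed
    subject and repetition random intercepts.

    On convergence failure the model is refit without the repetition
    intercept and the result is flagged.  ``group`` holds the string labels
    ("autistic" / "non_autistic"); TAS is centred internally.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) < 2:
        raise DataError("both groups must be present in the design")
    if np.ptp(values) == 0:
        raise DataError("response is constant across all observations")
    df = pd.DataFrame({
        "y": values,
        "group_a": (group == "autistic").astype(float),
        "tas_c": np.asarray(tas, dtype=float) - np.mean(tas),
        "subject": np.asarray(subject_ids).astype(str),
        "repetition": np.asarray(repetition_ids).astype(str),
        "const_group": np.ones(len(values)),
    })

    def _fit(vc: dict[str, str]):
        model = sm.MixedLM.from_formula(
            "y ~ group_a + tas_c", groups="const_group", vc_formula=vc,
            data=df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True)

    vc_full = {"subject": "0 + C(subject)", "repetition": "0 + C(repetition)"}
    converged = True
    try:
        res = _fit(vc_full)
        if not np.isfinite(res.bse["group_a"]) or not np.isfinite(
                res.bse["tas_c"]):
            raise ValueError("non-finite standard errors")
    except Exception:
        converged = False
        res = _fit({"subject": "0 + C(subject)"})

    stats = {}
    for effect, term in (("group", "group_a"), ("tas", "tas_c")):
        coef = res.params[term]
        se = res.bse[term]
        t = coef / se if se > 0 else np.sign(coef) * np.inf
        stats[effect] = t
    return UnitModelResult(
        unit_id=unit_id, timepoint=timepoint,
        group_stat=float(stats["group"]), tas_stat=float(stats["tas"]),
        group_f=float(stats["group"] ** 2), tas_f=float(stats["tas"] ** 2),
        converged=converged)


# ---------------------------------------------------------------------------
# Collapsed (balanced-design) engine

def is_balanced(subject_ids: np.ndarray, repetition_ids: np.ndarray) -> bool:
    """True when every subject contributes every repetition exactly once."""
    table = pd.crosstab(pd.Series(subject_ids), pd.Series(repetition_ids))
    return bool((table.to_numpy() == 1).all())


def collapse_to_subjects(Y: np.ndarray, group: np.ndarray, tas: np.ndarray,
                         subject_ids: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average observations within subject: (S, units) means plus
    subject-level group indicator and TAS."""
    subjects, inverse = np.unique(np.asarray(subject_ids), return_inverse=True)
    S = len(subjects)
    counts = np.bincount(inverse, minlength=S).astype(float)
    Ybar = np.zeros((S, Y.shape[1]))
    np.add.at(Ybar, inverse, Y)
    Ybar /= counts[:, None]
    group_a = np.zeros(S)
    tas_s = np.zeros(S)
    first = np.full(S, -1)
    for i, s in enumerate(inverse):
        if first[s] < 0:
            first[s] = i
    group_a = (np.asarray(group)[first] == "autistic").astype(float)
    tas_s = np.asarray(tas, dtype=float)[first]
    return Ybar, group_a, tas_s


def _subject_level_stats(Ybar: np.ndarray, group_a: np.ndarray,
                         tas_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised OLS t statistics (group, TAS) on subject means.

    Returns two (units,) arrays.  Degenerate 0/0 cases (a unit constant
    across subjects) yield a statistic of 0; zero residual variance with a
    nonzero coefficient yields +/-inf.
    """
    S = len(group_a)
    X = np.column_stack([np.ones(S), group_a, tas_s - tas_s.mean()])
    if len(np.unique(group_a)) < 2:
        raise DataError("both groups must be present in the design")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Ybar)                     # (3, units)
    resid = Ybar - X @ beta
    dof = S - X.shape[1]
    if dof <= 0:
        raise DataError(f"need more than {X.shape[1]} subjects, got {S}")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t_group = beta[1] / np.sqrt(sigma2 * XtX_inv[1, 1])
        t_tas = beta[2] / np.sqrt(sigma2 * XtX_inv[2, 2])
    t_group = np.where(np.isnan(t_group), 0.0, t_group)
    t_tas = np.where(np.isnan(t_tas), 0.0, t_tas)
    return t_group, t_tas


def fit_units_balanced(Y: np.ndarray, group: np.ndarray, tas: np.ndarray,
                       subject_ids: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Group / TAS t statistics for all units of a balanced design at once."""
    Ybar, group_a, tas_s = collapse_to_subjects(Y, group, tas, subject_ids)
    return _subject_level_stats(Ybar, group_a, tas_s)


# ---------------------------------------------------------------------------
# Permutation null

def permutation_null(Y: np.ndarray, group: np.ndarray, tas: np.ndarray,
                     subject_ids: np.ndarray, n_permutations: int,
                     alpha: float, seed: int, pooling: str = "max",
                     ) -> tuple[dict[str, np.ndarray | float],
                                dict[str, np.ndarray]]:
    """Permutation thresholds for the group and TAS effects.

    Permutation acts at the participant level: for the group effect the
    subject group labels are reassigned (group sizes preserved); for the
    TAS effect the subject TAS values are permuted.  With ``pooling="max"``
    each permutation contributes the maximum |t| across the family and one
    threshold (the 1 - alpha quantile of that null) applies family-wide;
    with ``pooling="per_unit"`` each unit is thresholded against its own
    null distribution.

    Returns ``(thresholds, null)`` where ``thresholds[effect]`` is a scalar
    (max pooling) or a (units,) array, and ``null[effect]`` holds the null
    statistics (per permutation, or per permutation x unit).
    """
    if n_permutations < 100:
        raise ConfigurationError("n_permutations must be >= 100")
    if pooling not in ("max", "per_unit"):
        raise ConfigurationError(f"unknown pooling {pooling!r}")
    Ybar, group_a, tas_s = collapse_to_subjects(Y, group, tas, subject_ids)
    S = len(group_a)
    if S < 4:
        raise DataError("too few participants for permutation inference")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))

    null_group = np.empty((n_permutations, Ybar.shape[1]))
    null_tas = np.empty((n_permutations, Ybar.shape[1]))
    for b in range(n_permutations):
        perm_g = rng.permutation(S)
        t_g, _ = _subject_level_stats(Ybar, group_a[perm_g], tas_s)
        perm_t = rng.permutation(S)
        _, t_t = _subject_level_stats(Ybar, group_a, tas_s[perm_t])
        null_group[b] = np.abs(t_g)
        null_tas[b] = np.abs(t_t)

    thresholds: dict[str, np.ndarray | float] = {}
    null: dict[str, np.ndarray] = {}
    # Discrete upper order statistic ("higher") rather than an interpolated
    # quantile: the standard finite-permutation convention, never
    # anticonservative for any number of permutations.
    for effect, dist in (("group", null_group), ("tas", null_tas)):
        if pooling == "max":
            max_dist = dist.max(axis=1)
            thresholds[effect] = float(np.quantile(max_dist, 1 - alpha,
                                                   method="higher"))
            null[effect] = max_dist
        else:
            thresholds[effect] = np.quantile(dist, 1 - alpha, axis=0,
                                             method="higher")
            null[effect] = dist
    return thresholds, null


# ---------------------------------------------------------------------------
# Dataset slicing and the end-to-end runner

def _slice_features(dataset: Dataset, measure: str, condition: str,
                    emotion: str, timing_mode: str, units: list[int] | None,
                    peak_index: int) -> tuple[np.ndarray, list, pd.DataFrame]:
    """Response matrix (observations x features) for one analysis family.

    Features are units (peak / time_averaged) or unit x timepoint pairs
    (per_timepoint).  Spoken recordings are resampled to the configured
    uniform length before per-timepoint analysis; jerk series use their
    N - 4 valid frames.
    """
    if timing_mode not in TIMING_MODES:
        raise ConfigurationError(f"unknown timing_mode {timing_mode!r}")
    if timing_mode == "peak":
        if condition != "cued":
            raise ConfigurationError(
                "peak-frame analysis is defined only for the cued condition")
        if measure != "activation":
            raise ConfigurationError(
                "peak-frame analysis is defined only for activation")
    config = dataset.config
    pmap = dataset.participant_map
    target_frames = (config.frames_cued if condition == "cued"
                     else config.frames_spoken_mean)
    if measure == "jerk":
        target_frames -= 4

    rows, meta = [], []
    for rec in dataset.iter_recordings(condition=condition, emotion=emotion):
        if measure == "activation":
            series = rec.blendshapes
        else:
            series = recording_jerk(rec).values
        if units is not None:
            series = series[:, units]
        if timing_mode == "peak":
            values = peak_frame_activation(rec, peak_index=peak_index)
            if units is not None:
                values = values[units]
        elif timing_mode == "time_averaged":
            values = series.mean(axis=0)
        else:
            if series.shape[0] != target_frames:
                series = resample_to_length(series, target_frames)
            values = series.reshape(-1, order="F")   # unit-major blocks
        rows.append(values)
        p = pmap[rec.participant_id]
        meta.append((rec.participant_id, p.group, p.tas, rec.repetition))

    Y = np.vstack(rows)
    obs = pd.DataFrame(meta, columns=["participant_id", "group", "tas",
                                      "repetition"])
    unit_list = units if units is not None else list(
        range(Y.shape[1] if timing_mode != "per_timepoint" else
              Y.shape[1] // target_frames))
    if timing_mode == "per_timepoint":
        features = [(u, t + 1) for u in unit_list
                    for t in range(target_frames)]
    elif timing_mode == "peak":
        features = [(u, "peak") for u in unit_list]
    else:
        features = [(u, "averaged") for u in unit_list]
    return Y, features, obs


def run_mass_univariate(dataset: Dataset, measure: str, condition: str,
                        emotion: str, timing_mode: str = "time_averaged",
                        n_permutations: int = 1000, alpha: float = 0.05,
                        seed: int = 0, pooling: str = "max",
                        engine: str = "auto", units: list[int] | None = None,
                        peak_index: int = DEFAULT_PEAK_INDEX,
                        ) -> MassUnivariateResult:
    """Fit every unit of one analysis family and apply permutation
    thresholds.

    One family = one (measure, condition, emotion, timing_mode) slice; the
    significance mask marks features whose observed |statistic| exceeds the
    permutation threshold of their effect.
    """
    Y, features, obs = _slice_features(dataset, measure, condition, emotion,
                                       timing_mode, units, peak_index)
    group = obs["group"].to_numpy()
    tas = obs["tas"].to_numpy(dtype=float)
    subj = obs["participant_id"].to_numpy()
    reps = obs["repetition"].to_numpy()

    balanced = is_balanced(subj, reps)
    if engine == "auto":
        engine = "balanced" if balanced else "mixedlm"
    if engine == "balanced":
        if not balanced:
            raise DataError(
                "balanced engine requires a complete subject x repetition "
                "design")
        t_group, t_tas = fit_units_balanced(Y, group, tas, subj)
        converged = np.ones(Y.shape[1], dtype=bool)
    elif engine == "mixedlm":
        t_group = np.empty(Y.shape[1])
        t_tas = np.empty(Y.shape[1])
        converged = np.ones(Y.shape[1], dtype=bool)
        for j in range(Y.shape[1]):
            r = fit_unit_model(Y[:, j], group, tas, subj, reps,
                               unit_id=features[j][0],
                               timepoint=features[j][1])
            t_group[j], t_tas[j] = r.group_stat, r.tas_stat
            converged[j] = r.converged
    else:
        raise ConfigurationError(f"unknown engine {engine!r}")

    thresholds, null = permutation_null(
        Y, group, tas, subj, n_permutations=n_permutations, alpha=alpha,
        seed=seed, pooling=pooling)

    results = pd.DataFrame({
        "unit": [f[0] for f in features],
        "timepoint": [f[1] for f in features],
        "group_stat": t_group,
        "tas_stat": t_tas,
        "group_f": t_group ** 2,
        "tas_f": t_tas ** 2,
        "converged": converged,
    })
    for effect, stats in (("group", t_group), ("tas", t_tas)):
        thr = thresholds[effect]
        results[f"{effect}_threshold"] = thr
        results[f"{effect}_significant"] = np.abs(stats) > thr
    return MassUnivariateResult(
        results=results, thresholds=thresholds,
        n_permutations=n_permutations, alpha=alpha, pooling=pooling,
        measure=measure, condition=condition, emotion=emotion,
        timing_mode=timing_mode, null_max=null)
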