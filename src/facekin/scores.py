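"""Production indices and the differentiation-based recognition accuracy.

Three participant-level production indices are computed per condition
(cued / spoken) and measure (blendshape activation / landmark jerk):

* **mean level** — grand mean across timepoints, channels, repetitions and
  emotions;
* **precision** — for each channel, the mean over timepoints within each
  repetition, then the standard deviation of those means across
  repetitions; averaged over channels and negated, so that higher values
  indicate more consistent (precise) productions;
* **differentiation** — absolute difference between two emotions'
  per-channel means (averaged over repetitions and timepoints), averaged
  over channels; one score per emotion pair plus their mean.

Recognition accuracy per trial is the correct-emotion rating minus the
mean of the two incorrect-emotion ratings (range -10..10); a participant's
score is the mean over trials.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .blendshapes import EMOTIONS
from .kinematics import mean_over_time, recording_jerk
from .synthetic import Dataset
from .types import DataError

EMOTION_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(EMOTIONS, 2))


def _repetition_unit_means(rep_series: Sequence[np.ndarray]) -> np.ndarray:
    """(repetitions, units) matrix of per-repetition time means."""
    if len(rep_series) == 0:
        raise DataError("no repetitions supplied")
    return np.vstack([mean_over_time(np.atleast_2d(s)) for s in rep_series])


def precision_score(rep_series: Sequence[np.ndarray],
                    ddof: int = 1) -> float:
    """Negated across-repetition variability for one participant, emotion,
    condition and measure.

    Steps: (1) mean over timepoints per repetition per channel; (2) SD of
    those means across repetitions per channel (sample SD, ``ddof=1``, by
    default); (3) mean across channels; (4) negate, so higher = more
    precise.  Requires at least two repetitions.
    """
    means = _repetition_unit_means(rep_series)
    if means.shape[0] < 2:
        raise DataError("precision needs >= 2 repetitions")
    return float(-means.std(axis=0, ddof=ddof).mean())


def differentiation_score(emotion_unit_means: Mapping[str, np.ndarray],
                          ) -> dict[str, float]:
    """Per-pair and overall differentiation from per-emotion channel means.

    ``emotion_unit_means`` maps each of the three emotions to its
    (channels,) vector of means over repetitions and timepoints.  Returns
    ``{"anger-happiness": ..., "anger-sadness": ..., "happiness-sadness":
    ..., "overall": ...}`` where each pair score is the mean over channels
    of the absolute difference, and overall is the mean of the three pairs.
    """
    missing = [e for e in EMOTIONS if e not in emotion_unit_means]
    if missing:
        raise DataError(f"missing emotions for differentiation: {missing}")
    out: dict[str, float] = {}
    for e1, e2 in EMOTION_PAIRS:
        a = np.asarray(emotion_unit_means[e1], dtype=float)
        b = np.asarray(emotion_unit_means[e2], dtype=float)
        if a.shape != b.shape:
            raise DataError("emotion mean vectors differ in shape")
        out[f"{e1}-{e2}"] = float(np.abs(a - b).mean())
    out["overall"] = float(np.mean([out[f"{e1}-{e2}"]
                                    for e1, e2 in EMOTION_PAIRS]))
    return out


def mean_production_index(series_by_emotion: Mapping[str, Sequence[np.ndarray]],
                          ) -> float:
    """Grand mean of a measure across timepoints, channels, repetitions and
    emotions for one participant and condition.

    Computed as the mean of per-recording means (equal weight per
    recording), which coincides with the flat mean whenever recordings have
    equal length — as they do after resampling.
    """
    rec_means = [float(np.mean(s))
                 for reps in series_by_emotion.values() for s in reps]
    if not rec_means:
        raise DataError("no data for mean production index")
    return float(np.mean(rec_means))


def er_accuracy(ratings: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Differentiation-based recognition accuracy from trial ratings.

    ``ratings`` must contain ``participant_id``, ``target_emotion`` and the
    three columns ``rating_anger``, ``rating_happiness``, ``rating_sadness``
    (each in [0, 10]).  Per trial, accuracy is the target-emotion rating
    minus the mean of the two non-target ratings.  Returns the per-trial
    frame (with an ``accuracy`` column added) and the per-participant mean.
    """
    rating_cols = [f"rating_{e}" for e in EMOTIONS]
    values = ratings[rating_cols].to_numpy(dtype=float)
    if values.min() < 0 or values.max() > 10:
        bad = np.argwhere((values < 0) | (values > 10))[0]
        raise DataError(
            f"rating outside [0, 10] at row {bad[0]}, column "
            f"{rating_cols[bad[1]]}")
    target_idx = ratings["target_emotion"].map(
        {e: i for i, e in enumerate(EMOTIONS)}).to_numpy()
    if np.any(pd.isna(target_idx)):
        raise DataError("unknown target emotion in ratings table")
    n = len(ratings)
    correct = values[np.arange(n), target_idx]
    incorrect = (values.sum(axis=1) - correct) / 2.0
    per_trial = ratings.copy()
    per_trial["accuracy"] = correct - incorrect
    per_participant = per_trial.groupby("participant_id")["accuracy"].mean()
    return per_trial, per_participant


def _measure_series(dataset: Dataset, participant_id: str, condition: str,
                    emotion: str, measure: str) -> list[np.ndarray]:
    """Per-repetition (frames, channels) series for one cell."""
    reps = []
    for rep in range(1, dataset.config.n_repetitions + 1):
        rec = dataset.get_recording(participant_id, condition, emotion, rep)
        if measure == "activation":
            reps.append(rec.blendshapes)
        elif measure == "jerk":
            reps.append(recording_jerk(rec).values)
        else:
            raise DataError(f"unknown measure {measure!r}")
    return reps


def build_score_table(dataset: Dataset,
                      er_ratings: pd.DataFrame | None = None,
                      measures: Iterable[str] = ("activation", "jerk"),
                      ddof: int = 1) -> pd.DataFrame:
    """Participant x condition x measure table of production indices.

    Columns: mean_level; precision_overall and per-emotion precision;
    differentiation_overall and per-pair differentiation; er_accuracy
    (repeated across rows of a participant) when ``er_ratings`` is given.
    """
    er_means: pd.Series | None = None
    if er_ratings is not None:
        _, er_means = er_accuracy(er_ratings)

    rows = []
    for p in dataset.participants:
        for condition in dataset.config.conditions:
            for measure in measures:
                series_by_emotion = {
                    emotion: _measure_series(dataset, p.participant_id,
                                             condition, emotion, measure)
                    for emotion in dataset.config.emotions}
                row: dict[str, object] = {
                    "participant_id": p.participant_id, "group": p.group,
                    "condition": condition, "measure": measure,
                    "mean_level": mean_production_index(series_by_emotion),
                }
                prec = {emotion: precision_score(reps, ddof=ddof)
                        for emotion, reps in series_by_emotion.items()}
                for emotion, value in prec.items():
                    row[f"precision_{emotion}"] = value
                row["precision_overall"] = float(np.mean(list(prec.values())))
                if set(dataset.config.emotions) == set(EMOTIONS):
                    emo_means = {
                        emotion: _repetition_unit_means(reps).mean(axis=0)
                        for emotion, reps in series_by_emotion.items()}
                    diff = differentiation_score(emo_means)
                    row["differentiation_overall"] = diff["overall"]
                    for e1, e2 in EMOTION_PAIRS:
                        row[f"differentiation_{e1}_{e2}"] = diff[f"{e1}-{e2}"]
                if er_means is not None:
                    row["er_accuracy"] = er_means.get(p.participant_id,
                                                      np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def score_table_to_features(score_table: pd.DataFrame,
                            participants: pd.DataFrame | None = None,
                            ) -> pd.DataFrame:
    """Pivot a score table into the wide participant-level feature table
    used by the production-perception stage.

    Produces one row per participant with the 12 production features named
    ``{measure}_{mean|precision|differentiation}_{condition}`` plus, when
    ``participants`` (a metadata frame with aq/tas/iq columns) is supplied,
    the trait covariates, and the ``er_accuracy`` outcome if present.
    """
    frames = []
    for (condition, measure), sub in score_table.groupby(
            ["condition", "measure"]):
        sub = sub.set_index("participant_id")
        frames.append(pd.DataFrame({
            f"{measure}_mean_{condition}": sub["mean_level"],
            f"{measure}_precision_{condition}": sub["precision_overall"],
            f"{measure}_differentiation_{condition}":
                sub.get("differentiation_overall", np.nan),
        }))
    wide = pd.concat(frames, axis=1)
    meta = score_table.drop_duplicates("participant_id").set_index(
        "participant_id")
    wide.insert(0, "group", meta["group"])
    if "er_accuracy" in score_table.columns:
        wide["er_accuracy"] = meta["er_accuracy"]
    if participants is not None:
        pmeta = participants.set_index("participant_id")
        for col in ("aq", "tas", "iq"):
            wide[col] = pmeta[col]
    return wide.reset_index()
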