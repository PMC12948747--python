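"""Synthetic facial motion-capture data with known ground truth.

Generates complete datasets with the statistical structure the analysis
pipeline assumes: two groups of participants with group-conditional trait
scores; repetitions of three posed emotions in two conditions (beeped
"cued" trials with a neutral -> peak -> neutral profile, and variable-length
"spoken" trials with a sustained expression); crossed subject and
repetition random intercepts on blendshape activation; and configurable
group / alexithymia effects localised to chosen channels and time windows.

Landmark coordinates are produced as smooth trajectories coupled linearly
to the blendshape activations on a fixed synthetic avatar geometry, plus
measurement noise, so that landmark jerk inherits the activation dynamics.

All randomness derives from ``SimulationConfig.seed`` through independent
per-recording streams, so any recording can be regenerated in isolation and
the same config + seed is always bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .blendshapes import (
    ANALYSIS_BLENDSHAPES,
    EMOTIONS,
    GROUPS,
    N_BLENDSHAPES,
    N_LANDMARKS,
)
from .types import (
    AQ_RANGE,
    ConfigurationError,
    DEFAULT_TRAIT_PARAMS,
    EffectSpec,
    IQ_RANGE,
    ParticipantMeta,
    Recording,
    SimulationConfig,
    TAS_RANGE,
)

# Sub-stream tags keeping independent generators disjoint under one seed.
_STREAM_PARTICIPANTS = 1
_STREAM_RECORDING = 2
_STREAM_SUBJECT_INTERCEPT = 3
_STREAM_REPETITION_INTERCEPT = 4
_STREAM_SPOKEN_LENGTH = 5
_STREAM_ER = 6

# Resting muscle tone: baseline activation of every channel, keeping typical
# draws away from the [0, 1] clipping boundaries.
_BASELINE_ACTIVATION = 0.15

# Per-emotion blendshape amplitude patterns (added to baseline at template
# peak).  Channels follow conventional expression morphology: brow lowering
# for anger, smiling with cheek/eye involvement for happiness, inner-brow
# raise and frown for sadness.
_EMOTION_PATTERNS: dict[str, dict[str, float]] = {
    "anger": {
        "browDownLeft": 0.55, "browDownRight": 0.55,
        "eyeSquintLeft": 0.15, "eyeSquintRight": 0.15,
        "mouthPressLeft": 0.30, "mouthPressRight": 0.30,
        "noseSneerLeft": 0.20, "noseSneerRight": 0.20,
        "jawForward": 0.15,
    },
    "happiness": {
        "mouthSmileLeft": 0.60, "mouthSmileRight": 0.60,
        "cheekSquintLeft": 0.40, "cheekSquintRight": 0.40,
        "eyeSquintLeft": 0.25, "eyeSquintRight": 0.25,
        "mouthDimpleLeft": 0.25, "mouthDimpleRight": 0.25,
        "mouthUpperUpLeft": 0.30, "mouthUpperUpRight": 0.30,
        "browOuterUpLeft": 0.10, "browOuterUpRight": 0.10,
    },
    "sadness": {
        "browInnerUp": 0.50,
        "mouthFrownLeft": 0.45, "mouthFrownRight": 0.45,
        "mouthShrugLower": 0.25,
        "eyeBlinkLeft": 0.10, "eyeBlinkRight": 0.10,
        "mouthLowerDownLeft": 0.15, "mouthLowerDownRight": 0.15,
    },
}


def emotion_amplitudes(emotion: str) -> np.ndarray:
    """Peak activation amplitude per analysis blendshape for one emotion."""
    if emotion not in _EMOTION_PATTERNS:
        raise ConfigurationError(f"unknown emotion {emotion!r}")
    amp = np.zeros(N_BLENDSHAPES)
    for name, value in _EMOTION_PATTERNS[emotion].items():
        amp[ANALYSIS_BLENDSHAPES.index(name)] = value
    return amp


def cued_template(n_frames: int) -> np.ndarray:
    """Temporal profile of a cued trial, in [0, 1].

    The trial spans three equal beeped intervals: neutral for the first
    third, a raised-cosine ramp (one ninth of the trial, i.e. 1 s of 9 s)
    to a hold at the second beep, and a matching return to neutral at the
    third beep.
    """
    t = np.arange(n_frames) / n_frames          # trial fraction in [0, 1)
    ramp = 1.0 / 9.0
    template = np.zeros(n_frames)
    rising = (t >= 1 / 3) & (t < 1 / 3 + ramp)
    template[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - 1 / 3) / ramp))
    template[(t >= 1 / 3 + ramp) & (t < 2 / 3)] = 1.0
    falling = (t >= 2 / 3) & (t < 2 / 3 + ramp)
    template[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - 2 / 3) / ramp))
    return template


def spoken_template(n_frames: int) -> np.ndarray:
    """Sustained-expression profile: quick onset, long hold, quick offset."""
    t = np.arange(n_frames) / n_frames
    edge = 0.10
    template = np.ones(n_frames)
    rising = t < edge
    template[rising] = 0.5 * (1 - np.cos(np.pi * t[rising] / edge))
    falling = t >= 1 - edge
    template[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - (1 - edge)) / edge))
    return template


def _pid_key(participant_id: str) -> int:
    return zlib.crc32(participant_id.encode())


def _stream(config_seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, *keys]))


def generate_participants(config: SimulationConfig) -> list[ParticipantMeta]:
    """Draw 2 * n_per_group participants with group-conditional traits.

    Trait scores are normal draws from the configured per-group means/SDs,
    clipped to their instrument ranges (TAS 20-100, AQ 0-50, IQ 70-160).
    """
    if config.n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    sizes = (config.group_sizes if config.group_sizes is not None
             else (config.n_per_group, config.n_per_group))
    rng = _stream(config.seed, _STREAM_PARTICIPANTS)
    participants: list[ParticipantMeta] = []
    for group, n_group in zip(GROUPS, sizes):
        params = config.trait_params[group]
        prefix = "A" if group == "autistic" else "N"
        for i in range(n_group):
            tas = float(np.clip(rng.normal(*params["tas"]), *TAS_RANGE))
            aq = float(np.clip(rng.normal(*params["aq"]), *AQ_RANGE))
            iq = float(np.clip(rng.normal(*params["iq"]), *IQ_RANGE))
            age = float(np.clip(rng.normal(*params["age"]), 18.0, 80.0))
            sex = str(rng.choice(["female", "male"]))
            participants.append(ParticipantMeta(
                participant_id=f"{prefix}{i + 1:03d}", group=group,
                tas=tas, aq=aq, iq=iq, age=age, sex=sex))
    return participants


def _spoken_length(config: SimulationConfig, participant_id: str,
                   emotion: str, repetition: int) -> int:
    """Deterministic spoken-trial length: uniform integer jitter around the
    mean, independent of emotion."""
    if config.frames_spoken_jitter == 0:
        return config.frames_spoken_mean
    rng = _stream(config.seed, _STREAM_SPOKEN_LENGTH, _pid_key(participant_id),
                  EMOTIONS.index(emotion), repetition)
    return int(config.frames_spoken_mean + rng.integers(
        -config.frames_spoken_jitter, config.frames_spoken_jitter + 1))


def _subject_intercepts(config: SimulationConfig,
                        participant_id: str) -> np.ndarray:
    """Per-channel subject random intercepts, stable across recordings."""
    rng = _stream(config.seed, _STREAM_SUBJECT_INTERCEPT,
                  _pid_key(participant_id))
    return rng.normal(0.0, config.subject_sd, N_BLENDSHAPES)


def _repetition_intercepts(config: SimulationConfig,
                           repetition: int) -> np.ndarray:
    """Per-channel repetition random intercepts, shared across subjects
    (crossed with the subject intercepts)."""
    rng = _stream(config.seed, _STREAM_REPETITION_INTERCEPT, repetition)
    return rng.normal(0.0, config.repetition_sd, N_BLENDSHAPES)


def _avatar_geometry() -> tuple[np.ndarray, np.ndarray]:
    """Fixed synthetic avatar: 68 base landmark positions (centred at the
    face centroid, arbitrary avatar units) and the (68, 3, 44) linear
    coupling of landmark displacement to blendshape activation."""
    rng = np.random.default_rng(np.random.SeedSequence(6844))
    base = rng.normal(0.0, 1.0, (N_LANDMARKS, 3))
    base -= base.mean(axis=0)
    coupling = rng.normal(0.0, 1.0, (N_LANDMARKS, 3, N_BLENDSHAPES))
    return base, coupling


_AVATAR_BASE, _AVATAR_COUPLING = _avatar_geometry()
# (44, 68*3) layout for fast per-frame matmul; same coupling tensor.
_AVATAR_COUPLING_FLAT = np.ascontiguousarray(
    _AVATAR_COUPLING.reshape(N_LANDMARKS * 3, N_BLENDSHAPES).T)


def generate_recording(participant: ParticipantMeta, condition: str,
                       emotion: str, repetition: int,
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> Recording:
    """Simulate one posed-expression recording.

    Activation model per frame ``t`` and channel ``b``::

        a[t, b] = baseline + amp[b] * template[t] + u[b] + v[b]
                  + effects + eps[t, b],   clipped to [0, 1]

    with subject intercepts ``u`` (SD ``subject_sd``), repetition intercepts
    ``v`` (SD ``repetition_sd``) and white residual noise ``eps``
    (SD ``residual_sd``).  Matching ``EffectSpec`` entries add the group
    contrast (autistic participants only) and the TAS-linear shift inside
    their time window before clipping.

    Landmarks are the fixed avatar geometry displaced linearly by the
    activations (scale ``landmark_coupling``) plus white coordinate noise;
    jerk-targeted effects add an alternating-sign displacement whose fourth
    difference has magnitude ``group_effect`` (|Delta^4 a(-1)^t| = 16 a).
    """
    if condition not in config.conditions and condition not in ("cued", "spoken"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    if emotion not in EMOTIONS:
        raise ConfigurationError(f"unknown emotion {emotion!r}")
    if rng is None:
        rng = _stream(config.seed, _STREAM_RECORDING,
                      _pid_key(participant.participant_id),
                      ("cued", "spoken").index(condition),
                      EMOTIONS.index(emotion), repetition)

    if condition == "cued":
        n_frames = config.frames_cued
        template = cued_template(n_frames)
    else:
        n_frames = _spoken_length(config, participant.participant_id,
                                  emotion, repetition)
        template = spoken_template(n_frames)

    amp = emotion_amplitudes(emotion)
    activation = (_BASELINE_ACTIVATION
                  + template[:, None] * amp[None, :]
                  + _subject_intercepts(config, participant.participant_id)
                  + _repetition_intercepts(config, repetition))
    if config.residual_sd > 0:
        activation = activation + rng.normal(
            0.0, config.residual_sd, (n_frames, N_BLENDSHAPES))

    is_autistic = participant.group == "autistic"
    tas_delta = participant.tas - config.tas_center
    for eff in config.effects:
        if eff.emotion != emotion or eff.condition != condition:
            continue
        lo = eff.time_window[0] - 1
        hi = min(eff.time_window[1], n_frames)
        if lo >= hi:
            continue
        shift = eff.tas_slope * tas_delta + (eff.group_effect if is_autistic
                                             else 0.0)
        if eff.measure == "activation" and shift != 0.0:
            activation[lo:hi, list(eff.unit_ids)] += shift
    activation = np.clip(activation, 0.0, 1.0)

    displacement = activation @ _AVATAR_COUPLING_FLAT    # (frames, 68*3)
    landmarks = (_AVATAR_BASE[None, :, :]
                 + config.landmark_coupling
                 * displacement.reshape(n_frames, N_LANDMARKS, 3))
    if config.landmark_noise_sd > 0:
        landmarks = landmarks + rng.normal(
            0.0, config.landmark_noise_sd, landmarks.shape)
    for eff in config.effects:
        if (eff.measure != "jerk" or eff.emotion != emotion
                or eff.condition != condition):
            continue
        lo = eff.time_window[0] - 1
        hi = min(eff.time_window[1], n_frames)
        if lo >= hi:
            continue
        shift = eff.tas_slope * tas_delta + (eff.group_effect if is_autistic
                                             else 0.0)
        if shift != 0.0:
            zigzag = (shift / 16.0) * ((-1.0) ** np.arange(lo, hi))
            landmarks[lo:hi, list(eff.unit_ids), 0] += zigzag[:, None]

    return Recording(participant_id=participant.participant_id,
                     condition=condition, emotion=emotion,
                     repetition=repetition, blendshapes=activation,
                     landmarks=landmarks, frame_rate=config.frame_rate)


@dataclass
class Dataset:
    """A generated study: participants, a recording manifest, and lazily
    regenerable recordings.

    Recordings are produced on demand from independent per-recording random
    streams, so iteration never requires holding the full study (which at
    the emulated design is several GB) in memory, and any single recording
    can be regenerated in isolation, bit-identically.
    """

    config: SimulationConfig
    participants: list[ParticipantMeta]
    manifest: pd.DataFrame
    _cache: dict[tuple, Recording] = field(default_factory=dict, repr=False)

    @property
    def participant_map(self) -> dict[str, ParticipantMeta]:
        return {p.participant_id: p for p in self.participants}

    def get_recording(self, participant_id: str, condition: str,
                      emotion: str, repetition: int) -> Recording:
        key = (participant_id, condition, emotion, repetition)
        if key not in self._cache:
            rec = generate_recording(self.participant_map[participant_id],
                                     condition, emotion, repetition,
                                     self.config)
            if len(self._cache) < 256:
                self._cache[key] = rec
            return rec
        return self._cache[key]

    def iter_recordings(self, condition: str | None = None,
                        emotion: str | None = None) -> Iterator[Recording]:
        """Stream recordings in manifest order, regenerating each on the
        fly (no caching), so full-design iteration stays in constant
        memory."""
        pmap = self.participant_map
        for row in self.manifest.itertuples(index=False):
            if condition is not None and row.condition != condition:
                continue
            if emotion is not None and row.emotion != emotion:
                continue
            yield generate_recording(pmap[row.participant_id], row.condition,
                                     row.emotion, row.repetition, self.config)

    @property
    def n_recordings(self) -> int:
        return len(self.manifest)


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Generate a full study: one recording per participant x condition x
    emotion x repetition, with a manifest table."""
    participants = generate_participants(config)
    rows = []
    for p in participants:
        for condition in config.conditions:
            for emotion in config.emotions:
                for rep in range(1, config.n_repetitions + 1):
                    n_frames = (config.frames_cued if condition == "cued"
                                else _spoken_length(config, p.participant_id,
                                                    emotion, rep))
                    rows.append((p.participant_id, p.group, condition,
                                 emotion, rep, n_frames))
    manifest = pd.DataFrame(rows, columns=[
        "participant_id", "group", "condition", "emotion", "repetition",
        "n_frames"])
    return Dataset(config=config, participants=participants,
                   manifest=manifest)


@dataclass(frozen=True)
class ErLinkParams:
    """Ground-truth link from a production score to recognition ability.

    Each participant receives a latent discriminability ``d`` (expected
    correct-minus-incorrect rating difference on a recognition trial)::

        d = base + slope[group] * z(score) + N(0, latent_sd)

    where ``z(score)`` standardises the supplied production score across
    participants.  A zero slope in both groups makes the score and the
    realised accuracy independent.
    """

    slopes: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.0 for g in GROUPS})
    base: float = 3.0
    latent_sd: float = 0.5
    trial_noise_sd: float = 1.5
    n_trials: int = 108


def generate_er_ratings(participants: list[ParticipantMeta],
                        link_params: ErLinkParams,
                        seed: int,
                        scores: Mapping[str, float] | None = None,
                        ) -> pd.DataFrame:
    """Simulate the emotion-recognition rating task.

    Each participant completes ``n_trials`` trials (equal numbers of the
    three emotions, randomly ordered); on each, three 0-10 ratings are
    produced, with the correct-emotion rating elevated by the participant's
    latent discriminability.  Returns a tidy frame with one row per trial:
    participant_id, trial (1-based), target_emotion and the three ratings.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_ER]))
    n_trials = link_params.n_trials
    if n_trials % len(EMOTIONS) != 0:
        raise ConfigurationError("n_trials must be divisible by 3")
    if scores is not None:
        values = np.array([scores[p.participant_id] for p in participants])
        sd = values.std()
        z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    else:
        z = np.zeros(len(participants))

    rows = []
    for p, z_i in zip(participants, z):
        d = (link_params.base + link_params.slopes[p.group] * z_i
             + rng.normal(0.0, link_params.latent_sd))
        targets = np.repeat(EMOTIONS, n_trials // len(EMOTIONS))
        targets = rng.permutation(targets)
        for trial, target in enumerate(targets, start=1):
            ratings = {}
            for emo in EMOTIONS:
                mu = 5.0 + (d / 2 if emo == target else -d / 2)
                ratings[emo] = float(np.clip(
                    mu + rng.normal(0.0, link_params.trial_noise_sd),
                    0.0, 10.0))
            rows.append((p.participant_id, trial, target,
                         ratings["anger"], ratings["happiness"],
                         ratings["sadness"]))
    return pd.DataFrame(rows, columns=[
        "participant_id", "trial", "target_emotion",
        "rating_anger", "rating_happiness", "rating_sadness"])


#: Canonical production-feature names used by the production-perception stage.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{measure}_{kind}_{condition}"
    for measure in ("jerk", "activation")
    for kind in ("mean", "precision", "differentiation")
    for condition in ("cued", "spoken"))

TRAIT_FEATURES: tuple[str, ...] = ("aq", "tas", "iq")


def generate_feature_table(n_per_group: int, seed: int,
                           link_feature: str = "jerk_precision_spoken",
                           link_slopes: Mapping[str, float] | None = None,
                           base_accuracy: float = 3.0,
                           noise_sd: float = 1.0,
                           feature_correlation: float = 0.5) -> pd.DataFrame:
    """Directly simulate the participant-level feature table.

    Emulates the summary stage of the pipeline — 12 production features
    (mean / precision / differentiation of jerk and activation, cued and
    spoken), trait scores, and recognition accuracy — without generating
    frame-level recordings, so selection / regression recovery can be
    studied at large n.  Features within a measure share a common factor
    (weight ``feature_correlation``) to emulate the collinearity of real
    production summaries.  The outcome is linear in the standardised
    ``link_feature`` with a per-group slope, plus N(0, noise_sd) noise.
    """
    if link_feature not in FEATURE_NAMES:
        raise ConfigurationError(f"unknown feature {link_feature!r}")
    link_slopes = dict(link_slopes or {g: 0.0 for g in GROUPS})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    rows = []
    for group in GROUPS:
        traits = DEFAULT_TRAIT_PARAMS[group]
        for i in range(n_per_group):
            factor = {m: rng.normal() for m in ("jerk", "activation")}
            feats = {}
            for name in FEATURE_NAMES:
                measure = name.split("_")[0]
                feats[name] = (feature_correlation * factor[measure]
                               + np.sqrt(1 - feature_correlation ** 2)
                               * rng.normal())
            feats["aq"] = float(np.clip(rng.normal(*traits["aq"]), *AQ_RANGE))
            feats["tas"] = float(np.clip(rng.normal(*traits["tas"]), *TAS_RANGE))
            feats["iq"] = float(np.clip(rng.normal(*traits["iq"]), *IQ_RANGE))
            feats["participant_id"] = f"{'A' if group == 'autistic' else 'N'}{i + 1:04d}"
            feats["group"] = group
            rows.append(feats)
    table = pd.DataFrame(rows)
    z = (table[link_feature] - table[link_feature].mean()) / table[link_feature].std()
    slope = table["group"].map(link_slopes).astype(float)
    table["er_accuracy"] = (base_accuracy + slope * z
                            + rng.normal(0.0, noise_sd, len(table)))
    cols = (["participant_id", "group"] + list(FEATURE_NAMES)
            + list(TRAIT_FEATURES) + ["er_accuracy"])
    return table[cols]
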