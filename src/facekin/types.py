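"""Core domain types for facial motion-capture analysis.

All frame and repetition indices in user-facing structures are 1-based;
array storage is 0-based numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blendshapes import (
    CONDITIONS,
    EMOTIONS,
    GROUPS,
    N_BLENDSHAPES,
    N_LANDMARKS,
)

# Instrument score ranges: (Toronto Alexithymia Scale, Autism Quotient,
# two-subtest WASI-II IQ).
TAS_RANGE = (20.0, 100.0)
AQ_RANGE = (0.0, 50.0)
IQ_RANGE = (70.0, 160.0)


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class DataError(ValueError):
    """Input data violate a structural or range contract."""


@dataclass(frozen=True)
class ParticipantMeta:
    """Demographics and trait scores for one participant."""

    participant_id: str
    group: str                     # "autistic" | "non_autistic"
    tas: float                     # Toronto Alexithymia Scale, 20-100
    aq: float                      # Autism Quotient, 0-50
    iq: float                      # WASI-II two-subtest IQ, 70-160
    age: float                     # years
    sex: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(
                f"group must be one of {GROUPS}, got {self.group!r}")
        for name, value, (lo, hi) in (
            ("tas", self.tas, TAS_RANGE),
            ("aq", self.aq, AQ_RANGE),
            ("iq", self.iq, IQ_RANGE),
        ):
            if not lo <= value <= hi:
                raise ConfigurationError(
                    f"{name}={value} outside instrument range [{lo}, {hi}]")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect injected by the synthetic generator.

    ``group_effect`` is the autistic-minus-non-autistic shift on the
    measure's own scale, applied at ``unit_ids`` (blendshape indices for
    activation, landmark indices for jerk) within ``time_window`` (1-based,
    inclusive).  ``tas_slope`` is the per-TAS-unit linear shift, centred at
    the sample-average TAS.
    """

    measure: str                       # "activation" | "jerk"
    unit_ids: tuple[int, ...]
    time_window: tuple[int, int]
    emotion: str
    condition: str
    group_effect: float = 0.0
    tas_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.measure not in ("activation", "jerk"):
            raise ConfigurationError(f"unknown measure {self.measure!r}")
        if self.emotion not in EMOTIONS:
            raise ConfigurationError(f"unknown emotion {self.emotion!r}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if len(self.unit_ids) == 0:
            raise ConfigurationError("unit_ids must be non-empty")
        n_units = N_BLENDSHAPES if self.measure == "activation" else N_LANDMARKS
        if any(not 0 <= u < n_units for u in self.unit_ids):
            raise ConfigurationError(
                f"unit_ids must lie in [0, {n_units}) for {self.measure}")
        lo, hi = self.time_window
        if not 1 <= lo <= hi:
            raise ConfigurationError(
                f"time_window must be 1-based inclusive with start <= end, "
                f"got {self.time_window}")


#: Group-conditional trait distributions (mean, SD), clipped to instrument
#: ranges on draw.  Defaults follow matched adult autistic / non-autistic
#: samples (TAS 62.24 (12.11) vs 43.12 (13.58); AQ 33.24 (9.13) vs
#: 13.81 (7.62); IQ 112.60 (19.88) vs 116.85 (13.06); age ~30 vs ~28 years).
DEFAULT_TRAIT_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "non_autistic": {
        "tas": (43.12, 13.58),
        "aq": (13.81, 7.62),
        "iq": (116.85, 13.06),
        "age": (27.73, 10.69),
    },
    "autistic": {
        "tas": (62.24, 12.11),
        "aq": (33.24, 9.13),
        "iq": (112.60, 19.88),
        "age": (29.92, 9.67),
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic facial motion-capture study.

    Defaults reproduce the study design being emulated: two groups of ~25
    participants, 16 repetitions of each of 3 emotions in each of 2 posing
    conditions; cued recordings of 540 frames (9 s, beeps 3 s apart),
    spoken recordings of variable length near 382 frames.  The same config
    and seed always produce a bit-identical dataset.
    """

    n_per_group: int = 25
    #: Optional (autistic, non_autistic) sizes overriding ``n_per_group``;
    #: the emulated study had 25 autistic and 26 matched non-autistic adults.
    group_sizes: tuple[int, int] | None = None
    n_repetitions: int = 16
    emotions: tuple[str, ...] = EMOTIONS
    conditions: tuple[str, ...] = CONDITIONS
    frames_cued: int = 540
    frames_spoken_mean: int = 382
    frames_spoken_jitter: int = 40
    subject_sd: float = 0.04
    repetition_sd: float = 0.01
    residual_sd: float = 0.05
    landmark_noise_sd: float = 0.002
    landmark_coupling: float = 0.05
    tas_center: float = 52.68          # midpoint of the two group TAS means
    effects: tuple[EffectSpec, ...] = ()
    trait_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in
                                 DEFAULT_TRAIT_PARAMS.items()})
    frame_rate: float = 60.0           # metadata only (540 frames / 9 s)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_repetitions", "frames_cued",
                     "frames_spoken_mean"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.group_sizes is not None and any(
                n < 1 for n in self.group_sizes):
            raise ConfigurationError("group_sizes must be positive counts")
        if self.frames_spoken_jitter < 0:
            raise ConfigurationError("frames_spoken_jitter must be >= 0")
        for name in ("subject_sd", "repetition_sd", "residual_sd",
                     "landmark_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        unknown = set(self.emotions) - set(EMOTIONS)
        if unknown:
            raise ConfigurationError(f"unknown emotions: {sorted(unknown)}")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown conditions: {sorted(unknown)}")
        for eff in self.effects:
            frames = (self.frames_cued if eff.condition == "cued"
                      else self.frames_spoken_mean - self.frames_spoken_jitter)
            if eff.time_window[1] > frames:
                raise ConfigurationError(
                    f"effect time_window {eff.time_window} exceeds the "
                    f"guaranteed frame count ({frames}) of the "
                    f"{eff.condition} condition")


@dataclass
class Recording:
    """One posed expression: blendshape activations and landmark tracks."""

    participant_id: str
    condition: str
    emotion: str
    repetition: int                # 1-based
    blendshapes: np.ndarray        # (frames, 44), activations in [0, 1]
    landmarks: np.ndarray          # (frames, 68, 3), avatar units
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        self.blendshapes = np.asarray(self.blendshapes, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.condition not in CONDITIONS:
            raise DataError(f"unknown condition {self.condition!r}")
        if self.emotion not in EMOTIONS:
            raise DataError(f"unknown emotion {self.emotion!r}")
        if self.blendshapes.ndim != 2 or self.blendshapes.shape[1] != N_BLENDSHAPES:
            raise DataError(
                f"blendshapes must be (frames, {N_BLENDSHAPES}), "
                f"got {self.blendshapes.shape}")
        if (self.landmarks.ndim != 3
                or self.landmarks.shape[1:] != (N_LANDMARKS, 3)):
            raise DataError(
                f"landmarks must be (frames, {N_LANDMARKS}, 3), "
                f"got {self.landmarks.shape}")
        if self.landmarks.shape[0] != self.blendshapes.shape[0]:
            raise DataError("blendshape and landmark frame counts differ")
        if self.blendshapes.size and (self.blendshapes.min() < 0
                                      or self.blendshapes.max() > 1):
            raise DataError("activations must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.blendshapes.shape[0]


@dataclass(frozen=True)
class JerkSeries:
    """Per-landmark absolute jerk magnitudes over the valid frames.

    Four successive frame differences each shorten the series by one frame,
    so jerk is defined over ``source_frames - 4`` timepoints.
    """

    values: np.ndarray             # (source_frames - 4, 68), >= 0
    source_frames: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape[0] != self.source_frames - 4:
            raise DataError(
                f"jerk series must have source_frames - 4 = "
                f"{self.source_frames - 4} rows, got {values.shape[0]}")
        if values.size and values.min() < 0:
            raise DataError("jerk magnitudes must be nonnegative")
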