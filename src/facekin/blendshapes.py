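"""Canonical blendshape channel definitions.

ARKit-style face capture exposes 52 facial action channels ("blendshapes",
akin to facial action units such as ``browDownLeft``), each with an
activation in [0, 1] per frame.  The eight ``eyeLook*`` channels encode gaze
direction rather than expression and are excluded from analysis, leaving 44
channels.  This module fixes the channel order used everywhere in the
package: the canonical ARKit names, sorted alphabetically.
"""

from __future__ import annotations

# The 52 ARKit blendshape names (ARFaceAnchor blend-shape locations).
CAPTURE_BLENDSHAPES: tuple[str, ...] = tuple(sorted([
    "browDownLeft", "browDownRight", "browInnerUp",
    "browOuterUpLeft", "browOuterUpRight",
    "cheekPuff", "cheekSquintLeft", "cheekSquintRight",
    "eyeBlinkLeft", "eyeBlinkRight",
    "eyeLookDownLeft", "eyeLookDownRight",
    "eyeLookInLeft", "eyeLookInRight",
    "eyeLookOutLeft", "eyeLookOutRight",
    "eyeLookUpLeft", "eyeLookUpRight",
    "eyeSquintLeft", "eyeSquintRight",
    "eyeWideLeft", "eyeWideRight",
    "jawForward", "jawLeft", "jawOpen", "jawRight",
    "mouthClose",
    "mouthDimpleLeft", "mouthDimpleRight",
    "mouthFrownLeft", "mouthFrownRight",
    "mouthFunnel", "mouthLeft",
    "mouthLowerDownLeft", "mouthLowerDownRight",
    "mouthPressLeft", "mouthPressRight",
    "mouthPucker", "mouthRight",
    "mouthRollLower", "mouthRollUpper",
    "mouthShrugLower", "mouthShrugUpper",
    "mouthSmileLeft", "mouthSmileRight",
    "mouthStretchLeft", "mouthStretchRight",
    "noseSneerLeft", "noseSneerRight",
    "tongueOut",
    "mouthUpperUpLeft", "mouthUpperUpRight",
]))

# Gaze-direction channels: reflect where the eyes point, not what the face
# expresses; excluded from all analyses.
GAZE_BLENDSHAPES: tuple[str, ...] = tuple(
    name for name in CAPTURE_BLENDSHAPES if name.startswith("eyeLook")
)

# The analysis channels, in the package's fixed (alphabetical) order.
ANALYSIS_BLENDSHAPES: tuple[str, ...] = tuple(
    name for name in CAPTURE_BLENDSHAPES if name not in GAZE_BLENDSHAPES
)

N_CAPTURE_BLENDSHAPES: int = len(CAPTURE_BLENDSHAPES)
N_BLENDSHAPES: int = len(ANALYSIS_BLENDSHAPES)

# OpenFace-style facial landmark scheme: 68 tracked 3-D points on a common
# avatar face.
N_LANDMARKS: int = 68

LANDMARK_COLUMNS: tuple[str, ...] = tuple(
    f"lm{i:02d}_{axis}" for i in range(1, N_LANDMARKS + 1) for axis in "xyz"
)

EMOTIONS: tuple[str, ...] = ("anger", "happiness", "sadness")
CONDITIONS: tuple[str, ...] = ("cued", "spoken")
GROUPS: tuple[str, ...] = ("autistic", "non_autistic")

assert N_CAPTURE_BLENDSHAPES == 52
assert len(GAZE_BLENDSHAPES) == 8
assert N_BLENDSHAPES == 44


def blendshape_index(name: str) -> int:
    """Return the analysis-channel index (0-based) of a blendshape name."""
    try:
        return ANALYSIS_BLENDSHAPES.index(name)
    except ValueError:
        raise KeyError(f"unknown analysis blendshape: {name!r}") from None
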