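"""Shared configuration assets: landmark layout, canonical face template, domain map.

These are editable defaults, not claims about any external model's landmark
topology.  The canonical face template is a synthetic, roughly face-shaped
point set in image-normalized units (x, y in [0, 1], z a small relative
depth); it only needs to be non-coplanar so that per-frame affine fits are
well posed.
"""

from __future__ import annotations

import numpy as np

# --- landmark layout -------------------------------------------------------

FACE_LANDMARKS = [
    "head_top", "head_left", "head_right", "chin",
    "eye_l_outer", "eye_l_inner", "eye_r_inner", "eye_r_outer",
    "mouth_left", "mouth_right", "mouth_top", "mouth_bottom",
]

POSE_LANDMARKS = [
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
]

ALL_LANDMARKS = FACE_LANDMARKS + POSE_LANDMARKS

LANDMARK_CLASS = {name: "face" for name in FACE_LANDMARKS}
LANDMARK_CLASS.update({name: "pose" for name in POSE_LANDMARKS})

#: region -> landmark ids; "face" is the full face set, sub-regions overlap it.
DEFAULT_REGIONS = {
    "face": list(FACE_LANDMARKS),
    "head": ["head_top", "head_left", "head_right", "chin"],
    "eyes": ["eye_l_outer", "eye_l_inner", "eye_r_inner", "eye_r_outer"],
    "mouth": ["mouth_left", "mouth_right", "mouth_top", "mouth_bottom"],
    "body": list(POSE_LANDMARKS),
}

SHOULDER_LANDMARKS = ("left_shoulder", "right_shoulder")

#: synthetic canonical face template, image-normalized units.
CANONICAL_FACE = {
    "head_top":    (0.50, 0.20, 0.02),
    "head_left":   (0.38, 0.38, 0.00),
    "head_right":  (0.62, 0.38, 0.00),
    "chin":        (0.50, 0.58, 0.01),
    "eye_l_outer": (0.42, 0.35, 0.01),
    "eye_l_inner": (0.47, 0.35, 0.02),
    "eye_r_inner": (0.53, 0.35, 0.02),
    "eye_r_outer": (0.58, 0.35, 0.01),
    "mouth_left":  (0.45, 0.50, 0.01),
    "mouth_right": (0.55, 0.50, 0.01),
    "mouth_top":   (0.50, 0.48, 0.02),
    "mouth_bottom": (0.50, 0.52, 0.02),
}


def canonical_face_array(landmark_ids) -> np.ndarray:
    """Canonical template coordinates for ``landmark_ids``, shape (k, 3)."""
    return np.array([CANONICAL_FACE[name] for name in landmark_ids], dtype=float)


# --- semantic domains ------------------------------------------------------

#: Question -> domain map over the 23 interview questions.  Only the
#: self_emotion membership (questions 14, 17, 20, 23) is attested by the study
#: protocol; the remaining memberships are a plausible placeholder partition
#: and are meant to be overridden per deployment.
DEFAULT_DOMAIN_MAP = {
    "narrative_detail": [1, 2, 3, 4],
    "factual_memory": [5, 6, 7, 8],
    "thematic_understanding": [9, 10, 11],
    "character_emotion": [12, 13, 15, 16],
    "self_emotion": [14, 17, 20, 23],
    "preferences_positive": [18, 19],
    "preferences_negative": [21, 22],
}

N_QUESTIONS = 23
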