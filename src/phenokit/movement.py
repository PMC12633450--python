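"""Landmark-series quality control, normalization, and movement quantification.

The pipeline mirrors how framewise displacement is derived from video
landmark estimates:

1. QC masking on the raw coordinates — frames are dropped for a landmark when
   any covering 2-second window has more than 10% missing values, or when any
   covering 10-frame window shows excessive x-coordinate jitter (sample SD
   above 0.1 for face landmarks, 0.01 for pose landmarks).
2. Geometric normalization — face landmarks are aligned per frame to a
   canonical template by a least-squares affine map (removing head rotation,
   translation and scale); body landmarks are divided by the per-frame
   inter-shoulder distance (removing body size and camera distance).
3. Framewise displacement — per landmark, the 3D Euclidean distance between
   consecutive valid frames; displacements are averaged over time per
   landmark, then across the landmarks of each anatomical region, and the
   natural log of the region mean is the modeling variable.

Gaps are skipped, never interpolated: a frame pair contributes only when both
endpoints are valid for that landmark.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _assets

__all__ = [
    "LandmarkSeries",
    "QCConfig",
    "RegionSummary",
    "mask_missing_windows",
    "mask_jitter",
    "combine_validity",
    "align_face_affine",
    "normalize_body_scale",
    "region_displacement_summary",
    "movement_pipeline",
    "read_landmarks_csv",
    "movement_table",
]

logger = logging.getLogger(__name__)

DISTANCE_EPSILON = 1e-9  # inter-shoulder distances at or below this are degenerate


@dataclass
class LandmarkSeries:
    """Uniformly sampled 3D landmark trajectories for one participant.

    ``coords`` has shape (n_frames, n_landmarks, 3); ``present`` flags
    (n_frames, n_landmarks) mark frames where the landmark was estimated —
    coordinates of absent frames are ignored by every computation.
    """

    participant_id: str
    fps: float
    coords: np.ndarray
    present: np.ndarray
    landmark_ids: list[str]
    landmark_class: dict[str, str] = field(default_factory=lambda: dict(_assets.LANDMARK_CLASS))
    regions: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in _assets.DEFAULT_REGIONS.items()})

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_landmarks, 3)")
        if self.present.shape != self.coords.shape[:2]:
            raise ValueError("present mask must have shape (n_frames, n_landmarks)")
        if len(self.landmark_ids) != self.coords.shape[1]:
            raise ValueError("landmark_ids length must match coords")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def index_of(self, landmark_id: str) -> int:
        return self.landmark_ids.index(landmark_id)

    def classes(self) -> np.ndarray:
        """Per-landmark class array ('face' / 'pose')."""
        return np.array([self.landmark_class[l] for l in self.landmark_ids])

    def copy(self) -> "LandmarkSeries":
        return replace(self, coords=self.coords.copy(), present=self.present.copy())

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (one row per frame x landmark), CSV-ready."""
        T, L = self.present.shape
        frames = np.repeat(np.arange(T), L)
        lms = np.tile(np.arange(L), T)
        lm_ids = np.array(self.landmark_ids)[lms]
        classes = self.classes()[lms]
        region_of: dict[str, str] = {}
        for region, members in self.regions.items():
            for m in members:
                # sub-regions overlap the broad 'face' set; keep the most specific
                if m not in region_of or region_of[m] == "face":
                    region_of[m] = region
        return pd.DataFrame({
            "participant_id": self.participant_id,
            "frame": frames,
            "landmark_id": lm_ids,
            "landmark_class": classes,
            "region": [region_of.get(l, "") for l in lm_ids],
            "x": self.coords[frames, lms, 0],
            "y": self.coords[frames, lms, 1],
            "z": self.coords[frames, lms, 2],
            "present": self.present[frames, lms].astype(int),
        })


def read_landmarks_csv(path, fps: float = 30.0) -> dict[str, LandmarkSeries]:
    """Read a long-format landmarks CSV into one series per participant."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    out: dict[str, LandmarkSeries] = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        lm_ids = list(pd.unique(sub["landmark_id"]))
        lm_index = {l: i for i, l in enumerate(lm_ids)}
        T = int(sub["frame"].max()) + 1
        coords = np.zeros((T, len(lm_ids), 3))
        present = np.zeros((T, len(lm_ids)), dtype=bool)
        fi = sub["frame"].to_numpy(int)
        li = sub["landmark_id"].map(lm_index).to_numpy(int)
        coords[fi, li, 0] = sub["x"].to_numpy(float)
        coords[fi, li, 1] = sub["y"].to_numpy(float)
        coords[fi, li, 2] = sub["z"].to_numpy(float)
        present[fi, li] = sub["present"].to_numpy(int) == 1
        classes = dict(zip(sub["landmark_id"], sub["landmark_class"]))
        regions: dict[str, list[str]] = {}
        for lm, reg in dict(zip(sub["landmark_id"], sub["region"])).items():
            if isinstance(reg, str) and reg:
                regions.setdefault(reg, []).append(lm)
        if not regions:
            regions = {k: list(v) for k, v in _assets.DEFAULT_REGIONS.items()}
        out[pid] = LandmarkSeries(pid, fps, coords, present, lm_ids,
                                  landmark_class=classes, regions=regions)
    return out


@dataclass(frozen=True)
class QCConfig:
    """Sliding-window quality-control thresholds (raw coordinate units)."""

    missing_window_seconds: float = 2.0
    missing_fraction_max: float = 0.10
    jitter_window_frames: int = 10
    jitter_threshold_face: float = 0.1
    jitter_threshold_pose: float = 0.01

    def __post_init__(self) -> None:
        if min(self.missing_window_seconds, self.missing_fraction_max,
               self.jitter_threshold_face, self.jitter_threshold_pose) <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.jitter_window_frames < 1:
            raise ValueError("jitter window must span at least one frame")


def _windows(n: int, w: int) -> np.ndarray:
    """Start indices of length-``w`` sliding windows (step 1); a series
    shorter than ``w`` yields the single truncated full-series window."""
    if n <= w:
        return np.array([0])
    return np.arange(n - w + 1)


def _spread_violations(violate: np.ndarray, w: int, n: int) -> np.ndarray:
    """(n_windows, L) window violations -> (n, L) frame invalidity.

    A frame is invalidated when any window covering it violates.
    """
    n_win = violate.shape[0]
    w_eff = n if n <= w else w
    invalid = np.zeros((n, violate.shape[1]), dtype=bool)
    for s in range(n_win):
        hit = violate[s]
        if hit.any():
            invalid[s:s + w_eff, hit] = True
    return invalid


def mask_missing_windows(series: LandmarkSeries, qc: QCConfig | None = None) -> np.ndarray:
    """Validity mask from the missing-data rule.

    A frame is invalid for a landmark iff any covering sliding window (length
    ``fps * missing_window_seconds``, step one frame, truncated when the
    series is shorter) has a fraction of missing frames strictly above
    ``missing_fraction_max``.  Absent frames are always invalid.
    """
    qc = qc or QCConfig()
    T, L = series.present.shape
    if T == 0:
        return np.zeros((0, L), dtype=bool)
    w = max(1, int(round(series.fps * qc.missing_window_seconds)))
    missing = (~series.present).astype(float)
    starts = _windows(T, w)
    w_eff = min(w, T)
    csum = np.concatenate([np.zeros((1, L)), np.cumsum(missing, axis=0)])
    frac = (csum[starts + w_eff] - csum[starts]) / w_eff
    violate = frac > qc.missing_fraction_max
    invalid = _spread_violations(violate, w, T)
    return series.present & ~invalid


def mask_jitter(series: LandmarkSeries, qc: QCConfig | None = None) -> np.ndarray:
    """Validity mask from the jitter rule.

    A frame is invalid for a landmark iff any covering 10-frame window has a
    sample standard deviation (ddof=1, over present frames only) of the
    x-coordinate above the class threshold (face 0.1, pose 0.01).  Windows
    with fewer than two present frames impose no exclusion.
    """
    qc = qc or QCConfig()
    T, L = series.present.shape
    if T == 0:
        return np.zeros((0, L), dtype=bool)
    w = qc.jitter_window_frames
    classes = series.classes()
    thresh = np.where(classes == "face", qc.jitter_threshold_face,
                      qc.jitter_threshold_pose)

    x = np.where(series.present, series.coords[:, :, 0], 0.0)
    p = series.present.astype(float)
    starts = _windows(T, w)
    w_eff = min(w, T)

    def wsum(arr):
        c = np.concatenate([np.zeros((1, L)), np.cumsum(arr, axis=0)])
        return c[starts + w_eff] - c[starts]

    cnt = wsum(p)
    s1 = wsum(x)
    s2 = wsum(x * x)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - s1 * s1 / np.where(cnt > 0, cnt, 1.0)) / np.maximum(cnt - 1, 1)
        var = np.maximum(var, 0.0)
        std = np.sqrt(var)
    violate = (cnt >= 2) & (std > thresh[None, :])
    invalid = _spread_violations(violate, w, T)
    return series.present & ~invalid


def combine_validity(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """A frame passes overall QC only if it passes both checks (logical AND)."""
    m1 = np.asarray(m1, dtype=bool)
    m2 = np.asarray(m2, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError(f"mask shape mismatch: {m1.shape} vs {m2.shape}")
    return m1 & m2


def qc_mask(series: LandmarkSeries, qc: QCConfig | None = None) -> np.ndarray:
    """Combined missing-window and jitter validity mask."""
    return combine_validity(mask_missing_windows(series, qc), mask_jitter(series, qc))


def align_face_affine(
    series: LandmarkSeries,
    canonical: Mapping[str, Sequence[float]] | None = None,
    min_landmarks: int = 4,
) -> LandmarkSeries:
    """Align face landmarks per frame to a canonical template.

    For each frame, a least-squares affine map ``p -> A p + b`` is fitted
    from the present face landmarks to their canonical positions, and applied
    to all face landmarks in the frame.  Frames with fewer than
    ``min_landmarks`` present face landmarks, or with a rank-deficient
    (coplanar/collinear) configuration, are marked invalid (face landmarks
    set absent).  Pose landmarks are untouched.
    """
    canonical = canonical if canonical is not None else _assets.CANONICAL_FACE
    out = series.copy()
    classes = series.classes()
    face_idx = np.flatnonzero(classes == "face")
    if face_idx.size == 0:
        return out
    targets = np.array([canonical[series.landmark_ids[i]] for i in face_idx], dtype=float)

    for t in range(series.n_frames):
        pres = series.present[t, face_idx]
        k = int(pres.sum())
        if k < min_landmarks:
            out.present[t, face_idx] = False
            continue
        P = series.coords[t, face_idx[pres], :]
        D = np.column_stack([P, np.ones(k)])
        M, _, rank, _ = np.linalg.lstsq(D, targets[pres], rcond=None)
        if rank < 4:
            out.present[t, face_idx] = False
            continue
        allP = np.column_stack([series.coords[t, face_idx, :], np.ones(face_idx.size)])
        out.coords[t, face_idx, :] = allP @ M
    return out


def normalize_body_scale(
    series: LandmarkSeries,
    shoulder_ids: tuple[str, str] = _assets.SHOULDER_LANDMARKS,
) -> LandmarkSeries:
    """Divide pose coordinates by the per-frame inter-shoulder distance.

    Frames where either shoulder is absent, or the shoulders are (near-)
    coincident, are flagged invalid for all pose landmarks rather than
    raising.
    """
    out = series.copy()
    classes = series.classes()
    pose_idx = np.flatnonzero(classes == "pose")
    if pose_idx.size == 0:
        return out
    try:
        li = series.index_of(shoulder_ids[0])
        ri = series.index_of(shoulder_ids[1])
    except ValueError as exc:
        raise ValueError(f"shoulder landmarks {shoulder_ids} not in series") from exc
    both = series.present[:, li] & series.present[:, ri]
    dist = np.linalg.norm(series.coords[:, li, :] - series.coords[:, ri, :], axis=1)
    ok = both & (dist > DISTANCE_EPSILON)
    bad = ~ok
    if bad.any():
        logger.debug("%s: %d frames lack a usable inter-shoulder distance",
                     series.participant_id, int(bad.sum()))
    out.coords[:, pose_idx, :] = np.where(
        ok[:, None, None], series.coords[:, pose_idx, :] / np.where(ok, dist, 1.0)[:, None, None],
        series.coords[:, pose_idx, :])
    out.present[bad[:, None] & np.isin(np.arange(series.n_landmarks), pose_idx)[None, :]] = False
    return out


@dataclass(frozen=True)
class RegionSummary:
    """Per-region movement summary in normalized coordinate units per frame."""

    mean_displacement: float
    log_mean_displacement: float  # natural log; NaN when the mean is 0
    n_valid_frame_pairs: int


def region_displacement_summary(
    series: LandmarkSeries,
    mask: np.ndarray | None = None,
    regions: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, RegionSummary]:
    """Framewise-displacement summary per anatomical region.

    Per landmark, displacement is the 3D Euclidean distance between
    consecutive frames where both endpoints are valid; the region score is
    the mean over the region's landmarks of each landmark's temporal mean
    (landmarks with no valid pair are left out).  Regions with no valid pair
    at all are omitted from the result; a region whose mean displacement is
    exactly zero gets ``log_mean_displacement = NaN`` with a warning.
    """
    if mask is None:
        mask = series.present
    mask = combine_validity(mask, series.present)
    regions = regions if regions is not None else series.regions

    disp = np.linalg.norm(np.diff(series.coords, axis=0), axis=2)  # (T-1, L)
    pair_ok = mask[:-1] & mask[1:]
    lm_mean = np.full(series.n_landmarks, np.nan)
    lm_pairs = pair_ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.where(pair_ok, disp, 0.0).sum(axis=0)
        nz = lm_pairs > 0
        lm_mean[nz] = sums[nz] / lm_pairs[nz]

    out: dict[str, RegionSummary] = {}
    index = {l: i for i, l in enumerate(series.landmark_ids)}
    for region, members in regions.items():
        idx = [index[m] for m in members if m in index]
        if not idx:
            continue
        means = lm_mean[idx]
        pairs = int(lm_pairs[idx].sum())
        means = means[np.isfinite(means)]
        if means.size == 0:
            continue
        score = float(means.mean())
        if score > 0:
            log_score = float(np.log(score))
        else:
            warnings.warn(f"region {region!r}: zero mean displacement, log undefined",
                          stacklevel=2)
            log_score = np.nan
        out[region] = RegionSummary(score, log_score, pairs)
    return out


def movement_pipeline(
    series: LandmarkSeries,
    qc: QCConfig | None = None,
    canonical: Mapping[str, Sequence[float]] | None = None,
    regions: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, RegionSummary]:
    """Full per-participant chain: QC masks -> align/normalize -> summary.

    QC runs on the raw coordinates (the jitter thresholds are calibrated to
    raw image-normalized units); geometric normalization follows, and frames
    invalidated by alignment or degenerate shoulder geometry are removed from
    the displacement average.
    """
    mask = qc_mask(series, qc)
    s = align_face_affine(series, canonical)
    s = normalize_body_scale(s) if any(c == "pose" for c in s.classes()) else s
    mask = combine_validity(mask, s.present)
    return region_displacement_summary(s, mask, regions)


def movement_table(
    series_list: Sequence[LandmarkSeries],
    qc: QCConfig | None = None,
    canonical: Mapping[str, Sequence[float]] | None = None,
    regions: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Wide movement feature table: one row per participant.

    Columns are ``movement_<region>_log`` (natural log of the region's mean
    framewise displacement; the regression variable) and
    ``movement_<region>_pairs``.
    """
    rows = []
    for s in series_list:
        summ = movement_pipeline(s, qc, canonical, regions)
        row: dict[str, object] = {"participant_id": s.participant_id}
        for region, rs in summ.items():
            row[f"movement_{region}_log"] = rs.log_mean_displacement
            row[f"movement_{region}_pairs"] = rs.n_valid_frame_pairs
        rows.append(row)
    return pd.DataFrame(rows)
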