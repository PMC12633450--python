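"""QC masking, geometric normalization, and displacement summaries."""

import numpy as np
import pytest

from conftest import make_series
from phenokit import _assets
from phenokit.movement import (QCConfig, align_face_affine, combine_validity,
                               mask_jitter, mask_missing_windows,
                               movement_pipeline, normalize_body_scale,
                               region_displacement_summary)


# --- brute-force oracles ---------------------------------------------------

def brute_missing_mask(present, fps, qc):
    """All-windows scan: a frame is invalid iff any covering window has
    missing fraction strictly above the threshold."""
    T, L = present.shape
    w = max(1, int(round(fps * qc.missing_window_seconds)))
    w_eff = min(w, T)
    valid = present.copy()
    for lm in range(L):
        for s in range(max(1, T - w_eff + 1)):
            window = present[s:s + w_eff, lm]
            if (~window).mean() > qc.missing_fraction_max:
                valid[s:s + w_eff, lm] = False
    return valid & present


def brute_jitter_mask(series, qc):
    T, L = series.present.shape
    w = qc.jitter_window_frames
    w_eff = min(w, T)
    classes = series.classes()
    valid = series.present.copy()
    for lm in range(L):
        thr = qc.jitter_threshold_face if classes[lm] == "face" else qc.jitter_threshold_pose
        for s in range(max(1, T - w_eff + 1)):
            pres = series.present[s:s + w_eff, lm]
            xs = series.coords[s:s + w_eff, lm, 0][pres]
            if len(xs) >= 2 and np.std(xs, ddof=1) > thr:
                valid[s:s + w_eff, lm] = False
    return valid & series.present


def random_series(rng, T=200, L=4):
    coords = rng.normal(0.5, 0.05, (T, L, 3))
    present = rng.random((T, L)) > 0.08
    ids = ["head_top", "eye_l_outer", "left_shoulder", "left_wrist"][:L]
    return make_series(coords, present, landmark_ids=ids)


# --- missing-window mask ---------------------------------------------------

def test_always_present_landmark_fully_valid():
    s = make_series(np.zeros((600, 1, 3)), landmark_ids=["head_top"])
    assert mask_missing_windows(s).all()


def test_missing_run_invalidates_window_reach():
    """A 31-frame gap (31/60 > 10%) invalidates every frame reachable by a
    violating 60-frame window."""
    present = np.ones((600, 1), dtype=bool)
    present[100:131, 0] = False
    s = make_series(np.zeros((600, 1, 3)), present, landmark_ids=["head_top"])
    mask = mask_missing_windows(s)
    # a 60-frame window violates iff it overlaps the gap by >= 7 frames:
    # starts 47..124, so frames 47..183 are inside some violating window
    assert not mask[47:184, 0].any()
    assert mask[:47, 0].all()
    assert mask[184:, 0].all()
    assert np.array_equal(mask, brute_missing_mask(present, 30.0, QCConfig()))


def test_exactly_ten_percent_missing_is_not_a_violation():
    """6 missing per 60-frame window is exactly 10%, not strictly above."""
    present = np.ones((600, 1), dtype=bool)
    present[::10, 0] = False  # 6 per 60 frames, evenly spread
    s = make_series(np.zeros((600, 1, 3)), present, landmark_ids=["head_top"])
    mask = mask_missing_windows(s)
    qc = QCConfig()
    assert np.array_equal(mask, brute_missing_mask(present, 30.0, qc))
    assert np.array_equal(mask[:, 0], present[:, 0])  # all present frames valid


def test_empty_series_yields_empty_mask():
    s = make_series(np.zeros((0, 2, 3)), landmark_ids=["head_top", "chin"])
    assert mask_missing_windows(s).shape == (0, 2)


def test_missing_mask_equals_brute_force_scan(rng):
    s = random_series(rng)
    qc = QCConfig()
    assert np.array_equal(mask_missing_windows(s, qc),
                          brute_missing_mask(s.present, s.fps, qc))


# --- jitter mask -----------------------------------------------------------

def test_constant_x_is_never_jitter():
    coords = np.tile([0.4, 0.5, 0.0], (300, 1, 1))
    s = make_series(coords, landmark_ids=["head_top"])
    assert mask_jitter(s).all()


def test_alternating_face_x_exceeds_face_threshold():
    """x alternating 0.0/0.3 has sample SD ~0.158 > 0.1 in 10-frame windows."""
    coords = np.zeros((100, 1, 3))
    coords[1::2, 0, 0] = 0.3
    s = make_series(coords, landmark_ids=["head_top"])
    assert not mask_jitter(s).any()


def test_small_pose_noise_stays_below_pose_threshold(rng):
    coords = np.zeros((200, 1, 3))
    coords[:, 0, 0] = rng.normal(0.5, 0.004, 200)
    s = make_series(coords, landmark_ids=["left_shoulder"])
    qc = QCConfig()
    mask = mask_jitter(s, qc)
    assert np.array_equal(mask, brute_jitter_mask(s, qc))
    assert mask.all()


def test_jitter_mask_equals_brute_force_scan(rng):
    s = random_series(rng)
    s.coords[:, :, 0] = rng.normal(0.5, 0.05, s.coords.shape[:2])  # face-jittery
    qc = QCConfig()
    assert np.array_equal(mask_jitter(s, qc), brute_jitter_mask(s, qc))


def test_window_with_fewer_than_two_present_frames_excludes_nothing():
    present = np.zeros((10, 1), dtype=bool)
    present[3, 0] = True
    coords = np.zeros((10, 1, 3))
    coords[3, 0, 0] = 5.0  # wild value, but SD undefined with one sample
    s = make_series(coords, present, landmark_ids=["head_top"])
    assert mask_jitter(s)[3, 0]


def test_tightening_thresholds_never_adds_valid_frames(rng):
    """Masking monotonicity in both QC thresholds."""
    s = random_series(rng)
    s.coords[:, :, 0] = rng.normal(0.5, 0.08, s.coords.shape[:2])
    loose = QCConfig()
    tight = QCConfig(missing_fraction_max=0.05, jitter_threshold_face=0.05,
                     jitter_threshold_pose=0.005)
    for fn in (mask_missing_windows, mask_jitter):
        ml, mt = fn(s, loose), fn(s, tight)
        assert not (mt & ~ml).any()


# --- combine ---------------------------------------------------------------

def test_combined_validity_is_set_intersection(rng):
    a = rng.random((50, 3)) > 0.5
    b = rng.random((50, 3)) > 0.5
    assert np.array_equal(combine_validity(a, b), a & b)
    with pytest.raises(ValueError, match="mismatch"):
        combine_validity(a, b[:10])


# --- affine alignment ------------------------------------------------------

def _face_series(n_frames, transform=None):
    canon = _assets.canonical_face_array(_assets.FACE_LANDMARKS)
    coords = np.tile(canon, (n_frames, 1, 1))
    if transform is not None:
        A, b = transform
        coords = coords @ A.T + b
    return make_series(coords, landmark_ids=list(_assets.FACE_LANDMARKS))


def test_alignment_of_canonical_frame_is_identity():
    s = _face_series(3)
    out = align_face_affine(s)
    canon = _assets.canonical_face_array(_assets.FACE_LANDMARKS)
    assert np.allclose(out.coords, np.tile(canon, (3, 1, 1)), atol=1e-10)


def test_alignment_undoes_rotation_translation_scale():
    th = np.deg2rad(30)
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0],
                  [0, 0, 1.0]])
    A = 1.7 * R
    b = np.array([0.3, -0.2, 0.05])
    s = _face_series(2, transform=(A, b))
    out = align_face_affine(s)
    canon = _assets.canonical_face_array(_assets.FACE_LANDMARKS)
    assert np.max(np.abs(out.coords - canon[None])) <= 1e-8


def test_alignment_recovers_any_invertible_affine(rng):
    """The affine family is closed: residual to canonical is ~0 for any
    invertible distortion."""
    for _ in range(5):
        A = rng.normal(0, 1, (3, 3)) + 2 * np.eye(3)
        if abs(np.linalg.det(A)) < 0.1:
            continue
        b = rng.normal(0, 0.5, 3)
        s = _face_series(1, transform=(A, b))
        out = align_face_affine(s)
        canon = _assets.canonical_face_array(_assets.FACE_LANDMARKS)
        assert np.max(np.abs(out.coords[0] - canon)) <= 1e-8


def test_degenerate_face_configuration_marks_frame_invalid():
    # coplanar points (all z equal, arranged on a line in xy) -> rank deficient
    s = _face_series(1)
    s.coords[0, :, 0] = np.arange(12) * 0.01
    s.coords[0, :, 1] = 0.5
    s.coords[0, :, 2] = 0.0
    out = align_face_affine(s)
    assert not out.present[0].any()


def test_too_few_present_landmarks_marks_frame_invalid():
    s = _face_series(1)
    s.present[0, 3:] = False
    out = align_face_affine(s)
    assert not out.present[0].any()


# --- body normalization ----------------------------------------------------

def _body_series(coords3, present=None):
    ids = ["left_shoulder", "right_shoulder", "left_wrist"]
    return make_series(coords3, present, landmark_ids=ids)


def test_normalization_divides_by_shoulder_distance():
    coords = np.array([[[0, 0, 0], [2, 0, 0], [1, 1, 0]]], dtype=float)
    out = normalize_body_scale(_body_series(coords))
    assert np.allclose(out.coords[0, 2], [0.5, 0.5, 0.0])


def test_normalized_coordinates_are_scale_invariant(rng):
    coords = rng.normal(0.5, 0.1, (20, 3, 3))
    a = normalize_body_scale(_body_series(coords.copy()))
    b = normalize_body_scale(_body_series(coords * 3.7))
    assert np.allclose(a.coords, b.coords, atol=1e-12)


def test_coincident_shoulders_invalidate_frame():
    coords = np.array([[[1, 1, 0], [1, 1, 0], [0, 0, 0]]], dtype=float)
    out = normalize_body_scale(_body_series(coords))
    assert not out.present[0].any()


# --- displacement summary --------------------------------------------------

def test_static_landmarks_yield_missing_log(recwarn):
    coords = np.tile([0.5, 0.5, 0.0], (50, 2, 1))
    s = make_series(coords, landmark_ids=["head_top", "chin"],
                    regions={"head": ["head_top", "chin"]})
    summ = region_displacement_summary(s)
    assert summ["head"].mean_displacement == 0.0
    assert np.isnan(summ["head"].log_mean_displacement)
    assert any("log undefined" in str(w.message) for w in recwarn.list)


def test_constant_velocity_gives_exact_mean_displacement():
    v = 0.013
    coords = np.zeros((100, 1, 3))
    coords[:, 0, 0] = np.arange(100) * v
    s = make_series(coords, landmark_ids=["head_top"],
                    regions={"head": ["head_top"]})
    summ = region_displacement_summary(s)
    assert summ["head"].mean_displacement == pytest.approx(v)
    assert summ["head"].n_valid_frame_pairs == 99


def test_region_score_averages_per_landmark_means():
    """Two landmarks with unequal per-landmark means a, b -> region (a+b)/2,
    even with unequal valid-pair counts."""
    coords = np.zeros((11, 2, 3))
    coords[:, 0, 0] = np.arange(11) * 0.01   # mean disp a = 0.01
    coords[:, 1, 0] = np.arange(11) * 0.03   # mean disp b = 0.03
    present = np.ones((11, 2), dtype=bool)
    present[6:, 1] = False                   # landmark 2 has fewer pairs
    s = make_series(coords, present, landmark_ids=["head_top", "chin"],
                    regions={"head": ["head_top", "chin"]})
    summ = region_displacement_summary(s)
    assert summ["head"].mean_displacement == pytest.approx((0.01 + 0.03) / 2)


def test_gap_pairs_are_skipped_not_interpolated():
    coords = np.zeros((5, 1, 3))
    coords[:, 0, 0] = [0.0, 0.1, 0.2, 0.3, 0.4]
    present = np.array([[True], [True], [False], [True], [True]])
    s = make_series(coords, present, landmark_ids=["head_top"],
                    regions={"head": ["head_top"]})
    summ = region_displacement_summary(s)
    # only pairs (0,1) and (3,4) contribute, each displacement 0.1
    assert summ["head"].n_valid_frame_pairs == 2
    assert summ["head"].mean_displacement == pytest.approx(0.1)


# --- pipeline invariances --------------------------------------------------

def test_body_summary_is_invariant_to_global_scaling(rng):
    ids = ["left_shoulder", "right_shoulder", "left_wrist", "right_wrist"]
    # motion small enough that the absolute-unit jitter QC passes at both scales
    coords = np.cumsum(rng.normal(0, 3e-4, (150, 4, 3)), axis=0) + 0.5
    coords[:, 1, 0] += 0.3  # keep shoulders apart
    regions = {"body": ids}
    a = movement_pipeline(make_series(coords.copy(), landmark_ids=ids, regions=regions))
    b = movement_pipeline(make_series(coords * 5.3, landmark_ids=ids, regions=regions))
    assert abs(a["body"].mean_displacement - b["body"].mean_displacement) <= 1e-10


def test_face_summary_is_invariant_to_rigid_motion(rng):
    """Applying one fixed rotation+translation to every frame leaves the
    post-alignment displacement unchanged."""
    ids = list(_assets.FACE_LANDMARKS)
    canon = _assets.canonical_face_array(ids)
    coords = canon[None] + np.cumsum(rng.normal(0, 0.002, (100, 12, 3)), axis=0)
    th = np.deg2rad(25)
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    moved = coords @ R.T + np.array([0.2, -0.1, 0.3])
    regions = {"face": ids}
    a = movement_pipeline(make_series(coords, landmark_ids=ids, regions=regions))
    b = movement_pipeline(make_series(moved, landmark_ids=ids, regions=regions))
    assert abs(a["face"].mean_displacement - b["face"].mean_displacement) <= 1e-8
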