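import numpy as np
import pandas as pd
import pytest

from phenokit import _assets
from phenokit.movement import LandmarkSeries


def make_series(coords, present=None, fps=30.0, landmark_ids=None,
                landmark_class=None, regions=None, pid="P00000"):
    """Build a LandmarkSeries from a (T, L, 3) array with sane defaults."""
    coords = np.asarray(coords, dtype=float)
    T, L, _ = coords.shape
    if present is None:
        present = np.ones((T, L), dtype=bool)
    if landmark_ids is None:
        landmark_ids = _assets.ALL_LANDMARKS[:L]
    if landmark_class is None:
        landmark_class = {l: _assets.LANDMARK_CLASS.get(l, "face") for l in landmark_ids}
    kwargs = {}
    if regions is not None:
        kwargs["regions"] = regions
    return LandmarkSeries(pid, fps, coords, present, list(landmark_ids),
                          landmark_class=landmark_class, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_participants():
    """Six-record cohort covering the presentation labels and a missing IQ."""
    return pd.DataFrame({
        "participant_id": ["A", "B", "C", "D", "E", "F"],
        "age": [8.0, 12.0, 15.0, 9.0, 16.0, 11.0],
        "sex": [0, 1, 0, 1, 0, 0],
        "iq_full": [90.0, 105.0, np.nan, 110.0, 99.0, 101.0],
        "presentation": ["Combined", "Inattentive", "None", "Hyperactive",
                         "None", "OtherUnspecified"],
        "asd": [1, 0, 0, 0, 0, 0],
        "adhd_inatt": [1, 1, 0, 0, 0, 0],
        "adhd_hyper": [1, 0, 0, 1, 0, 0],
        "excluded": [0, 0, 0, 0, 0, 1],
        "td": [0, 0, 1, 0, 1, 0],
    })
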