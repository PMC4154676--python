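import numpy as np
import pandas as pd
import pytest

from rdiconn.atlas import LabelAtlas
from rdiconn.motionfield import RigidMotionSeries
from rdiconn.synthgen import grid_affine


def random_rigid(rng: np.random.Generator, max_angle=0.05, max_trans=2.0) -> np.ndarray:
    """Random small rigid-body 4x4 transform."""
    from scipy.spatial.transform import Rotation

    M = np.eye(4)
    M[:3, :3] = Rotation.from_euler(
        "xyz", rng.uniform(-max_angle, max_angle, 3)
    ).as_matrix()
    M[:3, 3] = rng.uniform(-max_trans, max_trans, 3)
    return M


def make_series(mats, affine=None, reference_index=0) -> RigidMotionSeries:
    """RigidMotionSeries from raw matrices, normalising the reference frame."""
    mats = np.asarray(mats, dtype=float)
    ref_inv = np.linalg.inv(mats[reference_index])
    mats = mats @ ref_inv
    mats[reference_index] = np.eye(4)
    return RigidMotionSeries(mats, reference_index,
                             np.eye(4) if affine is None else affine)


def simple_atlas(labels: np.ndarray, affine=None) -> LabelAtlas:
    labels = np.asarray(labels).astype(int)
    ids = np.unique(labels[labels > 0])
    table = pd.DataFrame(
        {
            "region_id": ids,
            "long_name": [f"region-{i}" for i in ids],
            "short_name": [f"r{i}" for i in ids],
            "hemisphere": ["" for _ in ids],
            "merged_from": ["" for _ in ids],
        }
    )
    return LabelAtlas(labels, table, np.eye(4) if affine is None else affine)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Small shared phantom: (atlas, brain, wm, csf) on a 16^3 grid."""
    from rdiconn.synthgen import make_phantom

    return make_phantom(shape=(16, 16, 16), n_regions=6, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Small shared synthetic cohort with distinct rotation centres."""
    from rdiconn.pipeline import cohort_spec
    from rdiconn.synthgen import generate_cohort

    spec = cohort_spec(
        77, distinct_centers=True, n_per_group=(8, 8), n_frames=80,
        n_regions=8, grid_shape=(14, 14, 14),
    )
    return generate_cohort(spec, keep_images=True, compute_dvars=True)
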