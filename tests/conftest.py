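import math

import numpy as np
import pytest

import tractfa as tf


@pytest.fixture(scope="session")
def scheme30():
    """30 directions at b=1000 s/mm^2 plus one b=0, the study protocol."""
    return tf.make_gradient_scheme(30, b=1000.0, n_b0=1, seed=0)


@pytest.fixture(scope="session")
def straight_phantom():
    """Straight bundle along +x through a 40x20x8 grid of 2.5 mm voxels."""
    spec = tf.PhantomSpec(
        shape=(40, 20, 8),
        bundles=[tf.BundleSpec(kind="straight", label=5, radius=5.0,
                               start=(10.0, 25.0, 10.0), direction=(1, 0, 0),
                               length=80.0)],
    )
    field, labels = tf.make_phantom(spec)
    return spec, field, labels


@pytest.fixture(scope="session")
def arc_phantom():
    """Quarter-circle bundle, curvature radius 60 mm (24 voxels)."""
    spec = tf.PhantomSpec(
        shape=(40, 40, 8),
        bundles=[tf.BundleSpec(kind="arc", label=3, radius=4.0,
                               center=(15.0, 15.0, 10.0), arc_radius=60.0,
                               plane_u=(1, 0, 0), plane_v=(0, 1, 0),
                               theta_range=(0.0, math.pi / 2))],
    )
    field, labels = tf.make_phantom(spec)
    return spec, field, labels


@pytest.fixture(scope="session")
def straight_tracked(straight_phantom):
    spec, field, labels = straight_phantom
    fa = tf.fa_map(field)
    bundle = tf.track_parcel(labels, 5, field, fa, tf.TrackingParams(), name="body_cc_L")
    return spec, field, labels, fa, bundle


def seed_point_of(streamline: tf.Streamline, voxel_size: float = 2.5) -> np.ndarray:
    """Recover the seed (the unique point lying exactly on a voxel center)."""
    scaled = streamline.points / voxel_size
    on_center = np.all(np.abs(scaled - np.round(scaled)) < 1e-9, axis=1)
    assert on_center.any()
    return streamline.points[on_center][0]
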