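import numpy as np
import pytest

from renovasc.grid import VolumeGrid


def make_ellipsoid_mask(
    semi_axes_mm=(8.0, 5.0, 4.0),
    centre_mm=(0.0, 0.0, 0.0),
    spacing_um=250.0,
    rotation=None,
):
    """Analytically rasterized (optionally rotated) ellipsoid mask.

    ``rotation`` is a 3x3 matrix applied to the ellipsoid body frame, so the
    mask is generated directly in the rotated pose rather than resampled.
    """
    semi = np.asarray(semi_axes_mm, float)
    centre = np.asarray(centre_mm, float)
    R = np.eye(3) if rotation is None else np.asarray(rotation, float)
    pad = semi.max() + 0.5
    sp = spacing_um / 1000.0
    n = int(np.ceil(2 * pad / sp)) + 1
    origin = centre - pad
    ax = [origin[d] + np.arange(n) * sp for d in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([X - centre[0], Y - centre[1], Z - centre[2]], axis=-1)
    body = P @ R  # R^T applied to each point
    inside = np.sum((body / semi) ** 2, axis=-1) <= 1.0
    return VolumeGrid(inside, np.full(3, spacing_um), origin)


def rotation_about_z(theta_deg):
    t = np.radians(theta_deg)
    return np.array(
        [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )


def random_rotation(rng):
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def small_phantom():
    from renovasc.synthgen import generate_kidney_phantom

    return generate_kidney_phantom(spacing_um=300.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
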