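import numpy as np
import pytest
from hypothesis import settings

from bodycomp.phantom import PhantomSpec, make_phantom_slice
from bodycomp.segmentation import RoiPolygon

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: scaled-down phantom used wherever the full 512 grid would be wasteful
SMALL_SPEC = PhantomSpec(
    rows=160, cols=160, center=(80.0, 80.0), body_axes=(60.0, 45.0),
    subcut_thickness=10.0, muscle_thickness=8.0,
    visceral_ellipses=(((68.0, 80.0), (10.0, 7.0)),
                       ((94.0, 80.0), (9.0, 6.0))),
    noise_sd=0.0, seed=0,
)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless scaled-down phantom; session-scoped, treat as read-only."""
    return make_phantom_slice(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size 512x512 phantom with the default noise level."""
    return make_phantom_slice(PhantomSpec())


def random_simple_polygon(rng, n_min=3, n_max=10, lo=-5.0, hi=69.0):
    """Random star-shaped (hence simple) polygon with vertices in [lo, hi]."""
    n = int(rng.integers(n_min, n_max + 1))
    cx, cy = rng.uniform(lo + 10, hi - 10, size=2)
    while True:
        # a sorted-angle polygon is simple iff every edge stays inside its
        # angular wedge, i.e. all gaps are distinct and below pi
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
        gaps = np.diff(np.append(angles, angles[0] + 2 * np.pi))
        if gaps.min() > 0.05 and gaps.max() < 3.0:
            break
    radii = rng.uniform(2.0, (hi - lo) / 2.5, size=n)
    verts = np.column_stack([cx + radii * np.cos(angles),
                             cy + radii * np.sin(angles)])
    return RoiPolygon(vertices=verts, compartment="M")
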