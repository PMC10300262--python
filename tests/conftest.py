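import numpy as np
import pytest

from nucleomorph.efa import Contour
from nucleomorph.synth import ShapeParams, gen_nucleus_contour


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_contour(
    axes=(30.0, 24.0), lobe_order=4, eps=0.0, rotation=0.0, n_points=256, noise=0.0, rng=None
) -> Contour:
    return gen_nucleus_contour(
        ShapeParams(
            base_semi_axes=axes,
            lobe_order=lobe_order,
            lobe_amplitude=eps,
            rotation=rotation,
            boundary_noise_sd=noise,
        ),
        n_points,
        rng,
    )


def random_lobed_contour(rng, n_points=256) -> Contour:
    a = float(rng.uniform(20, 40))
    return make_contour(
        axes=(a, a * float(rng.uniform(0.6, 1.0))),
        lobe_order=int(rng.integers(2, 7)),
        eps=float(rng.uniform(0.0, 0.4)),
        rotation=float(rng.uniform(0, 2 * np.pi)),
        n_points=n_points,
    )


def polygon_is_simple(points: np.ndarray) -> bool:
    """Brute-force segment-intersection scan (O(n^2), for n <= ~512)."""
    n = len(points)
    segs = np.stack([points, np.roll(points, -1, axis=0)], axis=1)

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def intersects(p1, p2, p3, p4):
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent via wraparound
            if intersects(*segs[i], *segs[j]):
                return False
    return True
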