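"""Elliptical Fourier analysis: coefficients, sizes, EFC ratio, threshold."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleomorph.efa import (
    Contour,
    DysmorphiaThreshold,
    EFCResult,
    calibrate_threshold,
    classify_dysmorphic,
    contour_efc,
    efa_decompose,
    efa_reconstruct,
    efc_ratio,
    extract_contour,
    harmonic_sizes,
    resample_contour,
)

from .conftest import make_contour, random_lobed_contour


def fourier_integral_oracle(points: np.ndarray, K: int):
    """Dense numerical Fourier integration of x(l), y(l) over chord length.

    Independent oracle for the closed-form segment sums: interpolate the
    polygon piecewise-linearly at high resolution and integrate
    (2/T) * f(l) * cos/sin(2 pi k l / T) with the trapezoid rule.
    """
    closed = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    T = t[-1]
    dense = np.linspace(0.0, T, 200_001)
    x = np.interp(dense, t, closed[:, 0])
    y = np.interp(dense, t, closed[:, 1])
    coeffs = []
    for k in range(1, K + 1):
        ck = np.cos(2 * np.pi * k * dense / T)
        sk = np.sin(2 * np.pi * k * dense / T)
        coeffs.append(
            [
                (2 / T) * np.trapezoid(x * ck, dense),
                (2 / T) * np.trapezoid(x * sk, dense),
                (2 / T) * np.trapezoid(y * ck, dense),
                (2 / T) * np.trapezoid(y * sk, dense),
            ]
        )
    return np.array(coeffs)


class TestExtractContour:
    def test_disk_circumference(self):
        yy, xx = np.mgrid[0:21, 0:21]
        disk = (xx - 10) ** 2 + (yy - 10) ** 2 <= 8**2
        c = extract_contour(disk)
        assert c.perimeter() == pytest.approx(2 * np.pi * 8, rel=0.03)
        assert c.signed_area() > 0  # counterclockwise

    def test_square_area(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        c = extract_contour(mask)
        assert c.area() == pytest.approx(100, rel=0.05)

    def test_two_blobs_rejected(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:15, 5:15] = True
        mask[40:50, 40:50] = True
        with pytest.raises(ValueError, match="components"):
            extract_contour(mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_contour(np.zeros((32, 32), dtype=bool))


class TestResample:
    def test_square_equal_arc_fractions(self):
        # 20x20 square: degenerate-free, perimeter 80
        sq = np.array([[0, 0], [20, 0], [20, 20], [0, 20]], dtype=float)
        # need >=16 points for Contour: densify each edge
        dense = np.vstack(
            [
                sq[i] + (sq[(i + 1) % 4] - sq[i]) * np.linspace(0, 1, 5, endpoint=False)[:, None]
                for i in range(4)
            ]
        )
        c = resample_contour(Contour(dense), 64)
        # start point preserved, perimeter positions uniform
        assert np.allclose(c.points[0], [0, 0])
        closed = np.vstack([c.points, c.points[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        assert np.allclose(seg, 80 / 64, atol=1e-9)

    def test_perimeter_preserved(self):
        c = make_contour(eps=0.3, n_points=512)
        rs = resample_contour(c, 256)
        assert rs.perimeter() == pytest.approx(c.perimeter(), rel=0.01)

    def test_idempotent(self):
        # equal-arc spacing is preserved up to chord-vs-arc curvature error
        # (exact identity is impossible for polygonal chord length)
        c = make_contour(eps=0.2)
        once = resample_contour(c, 128)
        twice = resample_contour(once, 128)
        assert np.allclose(once.points, twice.points, atol=1e-2)
        thrice = resample_contour(twice, 128)
        assert np.allclose(twice.points, thrice.points, atol=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 64"):
            resample_contour(make_contour(), 32)


class TestDecompose:
    def test_circle_is_one_harmonic(self):
        c = make_contour(axes=(30.0, 30.0), n_points=512)
        sizes = harmonic_sizes(efa_decompose(c, K=15)).sizes
        assert sizes[0] == pytest.approx(30.0, abs=0.1)
        assert sizes[1:15].sum() <= 1e-3 * sizes[0]

    def test_coefficients_match_fourier_integral_oracle(self):
        c = make_contour(axes=(40.0, 20.0), eps=0.2, lobe_order=3, n_points=2048)
        got = efa_decompose(c, K=8).harmonics
        want = fourier_integral_oracle(c.points, 8)
        assert np.allclose(got, want, rtol=1e-3, atol=1e-3 * np.abs(want).max())

    def test_orientation_independent_sizes(self):
        c = make_contour(eps=0.25, lobe_order=5)
        s_ccw = harmonic_sizes(efa_decompose(c)).sizes
        s_cw = harmonic_sizes(efa_decompose(c.reversed())).sizes
        assert np.allclose(s_ccw, s_cw, rtol=1e-9)

    def test_duplicate_points_dropped(self):
        pts = make_contour(n_points=128).points
        doubled = np.repeat(pts, 2, axis=0)
        d1 = efa_decompose(Contour(doubled))
        d2 = efa_decompose(Contour(pts))
        assert np.allclose(d1.harmonics, d2.harmonics, atol=1e-9)


class TestReconstruct:
    @pytest.mark.parametrize("lobe_order", [2, 3, 4, 5, 6])
    def test_full_reconstruction_close(self, lobe_order):
        # dysmorphic-grade lobing (amplitude 0.2) at every lobe order <= 6
        src = resample_contour(
            make_contour(eps=0.2, lobe_order=lobe_order, n_points=512), 512
        )
        rec = efa_reconstruct(efa_decompose(src, K=15), n_points=512)
        # same chord-length parameterization start -> pointwise comparison valid
        dev = np.hypot(*(rec.points - src.points).T)
        assert dev.max() <= 0.5

    def test_single_harmonic_is_ellipse(self):
        d = efa_decompose(make_contour(eps=0.3, lobe_order=4))
        e = efa_reconstruct(d, n_points=256, K_use=1)
        # an ellipse centered at (A0, C0): affine-normalized radii constant
        h = d.harmonics[0].reshape(2, 2)
        centered = e.points - [d.A0, d.C0]
        params = np.linalg.solve(h.T, centered.T)  # recover (cos, sin) parameters
        assert np.allclose(np.hypot(*params), 1.0, atol=1e-9)

    def test_error_nonincreasing_in_K(self):
        # RMS (L2) error is monotone by orthogonality of the harmonics;
        # the max deviation can wiggle and is not asserted
        src = resample_contour(make_contour(eps=0.25, lobe_order=5, n_points=512), 512)
        d = efa_decompose(src, K=15)
        errs = []
        for k in range(1, 16):
            rec = efa_reconstruct(d, n_points=512, K_use=k)
            errs.append(float(np.sqrt(np.mean((rec.points - src.points) ** 2))))
        assert all(e2 <= e1 * (1 + 1e-9) for e1, e2 in zip(errs, errs[1:]))


class TestHarmonicSizes:
    @pytest.mark.parametrize(
        "quad, expected",
        [((2.0, 0.0, 0.0, 1.0), 2.0), ((0.0, 2.0, 1.0, 0.0), 2.0)],
    )
    def test_singular_value_cases(self, quad, expected):
        d = efa_decompose(make_contour())
        h = d.harmonics.copy()
        h[0] = quad
        from dataclasses import replace

        sizes = harmonic_sizes(replace(d, harmonics=h)).sizes
        assert sizes[0] == pytest.approx(expected, abs=1e-12)

    def test_rotation_invariant(self):
        c = make_contour(eps=0.2, lobe_order=5)
        rot = 37 * np.pi / 180
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        s1 = harmonic_sizes(efa_decompose(c)).sizes
        s2 = harmonic_sizes(efa_decompose(Contour(c.points @ R.T))).sizes
        assert np.allclose(s1, s2, rtol=1e-9)

    def test_amplitude_definition_labelled(self):
        d = efa_decompose(make_contour(eps=0.2))
        amp = harmonic_sizes(d, definition="amplitude")
        assert amp.definition == "amplitude"
        assert np.all(amp.sizes >= harmonic_sizes(d).sizes - 1e-12)


class TestEFCRatio:
    def test_simple_arithmetic(self):
        sizes = np.zeros(15)
        sizes[0], sizes[1], sizes[2] = 2.0, 0.1, 0.1
        from nucleomorph.efa import HarmonicSizes

        res = efc_ratio(HarmonicSizes(sizes=sizes))
        assert res.efc_ratio == pytest.approx(10.0)

    def test_circle_huge_ratio(self):
        res = contour_efc(make_contour(axes=(30.0, 30.0), n_points=512))
        assert res.efc_ratio >= 1e3

    def test_monotone_decreasing_in_lobe_amplitude(self):
        ratios = [
            contour_efc(make_contour(eps=eps, lobe_order=4)).efc_ratio
            for eps in (0.05, 0.1, 0.2, 0.3)
        ]
        assert all(r1 > r2 for r1, r2 in zip(ratios, ratios[1:]))


class TestInvariance:
    """EFC ratio is a pure shape statistic."""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_similarity_transforms(self, seed):
        rng = np.random.default_rng(seed)
        c = random_lobed_contour(rng)
        base = contour_efc(c).efc_ratio
        rot = float(rng.uniform(0, 2 * np.pi))
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        scale = float(rng.uniform(0.2, 5.0))
        shift = rng.uniform(-100, 100, 2)
        k = int(rng.integers(1, c.n_points))
        variants = [
            Contour(c.points @ R.T),
            Contour(c.points * scale),
            Contour(c.points + shift),
            Contour(np.roll(c.points, k, axis=0)),  # start-point shift
            c.reversed(),
        ]
        for v in variants:
            assert contour_efc(v).efc_ratio == pytest.approx(base, rel=1e-6)


class TestThreshold:
    def test_mean_of_pool(self):
        assert calibrate_threshold([1.0, 2.0, 3.0]).value == pytest.approx(2.0)
        assert calibrate_threshold([5.0]).value == pytest.approx(5.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([1.0, -2.0])
        with pytest.raises(ValueError):
            calibrate_threshold([])

    @pytest.mark.parametrize(
        "efc, expected", [(1.9, True), (2.0, True), (2.1, False)]
    )
    def test_tie_is_dysmorphic(self, efc, expected):
        r = EFCResult(efc_ratio=efc, K_used=15, size_1=1.0, denominator=1.0)
        t = DysmorphiaThreshold(value=2.0, pool_size=3)
        assert classify_dysmorphic(r, t) is expected
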