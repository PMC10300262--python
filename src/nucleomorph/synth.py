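"""Synthetic fluorescence scenes and contour populations with ground truth.

Emulates the imaging data this pipeline is built for: DAPI-stained nuclei
that are normal (near-elliptical), dysmorphic (lobed), micronucleated
(a small satellite chromatin body beside the primary nucleus) or
multinucleated (two or more near-primary-sized nuclei in one cell),
an actin channel delimiting cell boundaries, and a DNA-damage channel
with diffraction-blurred gamma-H2AX foci.  Also generates toy chromatin
loop files for the Hi-C summary stage.

Shape model: a base ellipse with radial cosine lobes,

    p(theta) = (1 + eps * cos(k * theta) + noise(theta)) * (a cos theta, b sin theta)

rotated into place.  Because the modulation is a positive single-valued
radial factor, every generated contour is star-shaped and therefore
simple (no self-intersection) as long as the factor stays positive,
which ``eps < 0.5`` plus bounded noise guarantees.  The lobe amplitude
``eps`` gives analytic control over harmonic content: larger ``eps``
means more power in harmonics >= 2 and a lower EFC ratio.

All randomness flows from one explicit ``numpy.random.Generator``; no
global state is touched, and identical seeds reproduce scenes bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .efa import Contour, contour_efc

__all__ = [
    "ShapeParams",
    "SceneConfig",
    "GroundTruthCell",
    "GroundTruth",
    "gen_nucleus_contour",
    "render_scene",
    "gen_borderline_pool",
    "gen_toy_loops",
    "write_bedpe",
]


@dataclass(frozen=True)
class ShapeParams:
    """Generative parameters for one nuclear contour.

    ``base_semi_axes`` are the ellipse semi-axes (a, b) in pixels;
    ``lobe_order`` k and ``lobe_amplitude`` eps set the radial cosine
    modulation; ``boundary_noise_sd`` adds smooth radial jitter
    (dimensionless fraction of the local radius).
    """

    base_semi_axes: tuple[float, float] = (30.0, 30.0)
    lobe_order: int = 4
    lobe_amplitude: float = 0.0
    rotation: float = 0.0
    boundary_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.base_semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if self.lobe_order < 2:
            raise ValueError("lobe order must be >= 2")
        if not 0.0 <= self.lobe_amplitude < 0.5:
            raise ValueError(
                "lobe amplitude must lie in [0, 0.5) to keep the contour simple"
            )
        if self.boundary_noise_sd < 0:
            raise ValueError("boundary noise sd must be non-negative")


@dataclass(frozen=True)
class SceneConfig:
    """Layout and imaging parameters for one rendered scene."""

    n_cells: int = 20
    fraction_micronucleated: float = 0.0
    fraction_multinucleated: float = 0.0
    fraction_dysmorphic: float = 0.0
    foci_rate: float = 0.0  # mean planted foci per nucleus (Poisson)
    psf_sigma: float = 1.5  # pixels
    poisson_scale: float = 1.0  # photons per intensity unit; 0 disables shot noise
    read_noise_sd: float = 2.0  # additive Gaussian, intensity units
    image_size: tuple[int, int] = (512, 512)
    nucleus_radius: float = 18.0  # mean primary-nucleus semi-axis, pixels
    background: float = 10.0
    foreground: float = 200.0
    focus_amplitude: float = 150.0  # peak above local background, pre-noise
    min_focus_separation_sigmas: float = 6.0
    normal_lobe_amplitude: float = 0.02
    dysmorphic_lobe_amplitude: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_micronucleated",
            "fraction_multinucleated",
            "fraction_dysmorphic",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class GroundTruthCell:
    """Planted truth for one cell: flags, masks, contours, foci."""

    cell_id: int
    micronucleated: bool
    multinucleated: bool
    dysmorphic: bool
    nucleus_labels: list[int]  # labels in GroundTruth.nucleus_mask
    micronucleus_labels: list[int]
    contours: list[Contour]
    shape_params: list[ShapeParams]
    focus_coords: list[np.ndarray]  # per nucleus, (n_i, 2) (x, y)

    @property
    def n_foci(self) -> int:
        return int(sum(len(fc) for fc in self.focus_coords))


@dataclass
class GroundTruth:
    cells: list[GroundTruthCell]
    nucleus_mask: np.ndarray  # int labels, 0 background
    cell_mask: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_nuclei(self) -> int:
        return int(sum(len(c.nucleus_labels) for c in self.cells))

    @property
    def n_foci(self) -> int:
        return int(sum(c.n_foci for c in self.cells))

    def to_frame(self) -> pd.DataFrame:
        """One row per cell, for CSV export."""
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "n_nuclei": [len(c.nucleus_labels) for c in self.cells],
                "micronucleated": [c.micronucleated for c in self.cells],
                "multinucleated": [c.multinucleated for c in self.cells],
                "dysmorphic": [c.dysmorphic for c in self.cells],
                "n_foci": [c.n_foci for c in self.cells],
            }
        )


def gen_nucleus_contour(
    params: ShapeParams, n_points: int = 256, rng: np.random.Generator | None = None
) -> Contour:
    """Sample a simple closed nuclear contour from the radial lobe model.

    Points are ordered counterclockwise with the first point not repeated.
    Boundary noise is drawn per point and circularly smoothed so the
    radial factor stays positive and the curve stays simple.
    """
    if n_points < 64:
        raise ValueError("need at least 64 contour points")
    params = ShapeParams(**vars(params)) if not isinstance(params, ShapeParams) else params
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    factor = 1.0 + params.lobe_amplitude * np.cos(params.lobe_order * theta)
    if params.boundary_noise_sd > 0:
        if rng is None:
            raise ValueError("boundary noise requested but no rng supplied")
        raw = rng.normal(0.0, params.boundary_noise_sd, n_points)
        # circular smoothing keeps the jitter low-frequency and the factor positive
        kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(np.tile(raw, 3), kernel, mode="same")[
            n_points : 2 * n_points
        ]
        factor = factor + smooth
    factor = np.clip(factor, 0.05, None)
    a, b = params.base_semi_axes
    x = factor * a * np.cos(theta)
    y = factor * b * np.sin(theta)
    cr, sr = np.cos(params.rotation), np.sin(params.rotation)
    pts = np.column_stack([cr * x - sr * y, sr * x + cr * y])
    return Contour(pts)


def _rasterize(contour: Contour, center: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the contour polygon translated to ``center`` (x, y)."""
    pts = contour.points + center[None, :]
    rr, cc = draw.polygon(pts[:, 1], pts[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radius: float,
    max_tries: int = 2000,
) -> np.ndarray:
    """Non-overlapping cell centers by rejection sampling with bounded retries."""
    h, w = shape
    margin = 2.2 * radius
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ValueError("image too small for the requested cell radius")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping cells; achieved {len(centers)} "
                f"after {max_tries} tries — enlarge image_size or reduce n_cells"
            )
        tries += 1
        cand = np.array(
            [rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)]
        )
        if all(np.hypot(*(cand - c)) >= 2 * margin for c in centers):
            centers.append(cand)
    return np.array(centers)


def _plant_foci(
    rng: np.random.Generator,
    mask: np.ndarray,
    rate: float,
    min_sep: float,
) -> np.ndarray:
    """Poisson-distributed focus centers inside an eroded nucleus mask.

    Enforces a minimum pairwise separation; if the nucleus cannot hold the
    drawn number at that separation the achieved (smaller) set is planted
    and recorded as truth.
    """
    if rate <= 0:
        return np.empty((0, 2))
    target = rng.poisson(rate)
    if target == 0:
        return np.empty((0, 2))
    interior = ndimage.binary_erosion(mask, iterations=4)
    ys, xs = np.nonzero(interior if interior.any() else mask)
    coords: list[np.ndarray] = []
    for _ in range(40 * target):
        if len(coords) >= target:
            break
        i = rng.integers(len(xs))
        cand = np.array([float(xs[i]), float(ys[i])])
        if all(np.hypot(*(cand - c)) >= min_sep for c in coords):
            coords.append(cand)
    return np.array(coords) if coords else np.empty((0, 2))


def render_scene(
    config: SceneConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Render co-registered nuclear / actin / foci channels plus ground truth.

    Returns float images; the nuclear and foci channels carry PSF blur,
    Poisson shot noise and Gaussian read noise.  Deterministic for a
    fixed ``SceneConfig`` (the seed lives in the config).
    """
    rng = np.random.default_rng(config.seed)
    shape = config.image_size
    r = config.nucleus_radius
    centers = _place_centers(rng, config.n_cells, shape, r)

    nucleus_mask = np.zeros(shape, dtype=np.int32)
    cell_mask = np.zeros(shape, dtype=np.int32)
    foci_truth = np.zeros(shape, dtype=float)
    cells: list[GroundTruthCell] = []
    next_label = 1
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]

    for cid, center in enumerate(centers, start=1):
        micro = rng.random() < config.fraction_micronucleated
        multi = rng.random() < config.fraction_multinucleated
        dys = rng.random() < config.fraction_dysmorphic
        eps = (
            config.dysmorphic_lobe_amplitude if dys else config.normal_lobe_amplitude
        )
        labels: list[int] = []
        micro_labels: list[int] = []
        contours: list[Contour] = []
        shape_params: list[ShapeParams] = []
        focus_coords: list[np.ndarray] = []

        def add_nucleus(params: ShapeParams, at: np.ndarray, is_micro: bool) -> None:
            nonlocal next_label
            cont = gen_nucleus_contour(params, 256, rng)
            m = _rasterize(cont, at, shape)
            m &= nucleus_mask == 0
            nucleus_mask[m] = next_label
            labels.append(next_label)
            if is_micro:
                micro_labels.append(next_label)
            contours.append(Contour(cont.points + at[None, :]))
            shape_params.append(params)
            coords = (
                np.empty((0, 2))
                if is_micro
                else _plant_foci(
                    rng,
                    m,
                    config.foci_rate,
                    config.min_focus_separation_sigmas * config.psf_sigma,
                )
            )
            focus_coords.append(coords)
            next_label += 1

        def primary_params(scale: float = 1.0) -> ShapeParams:
            a = scale * r * rng.uniform(0.9, 1.1)
            b = a * rng.uniform(0.75, 1.0)
            return ShapeParams(
                base_semi_axes=(a, b),
                lobe_order=int(rng.integers(3, 7)),
                lobe_amplitude=eps,
                rotation=rng.uniform(0, 2 * np.pi),
                boundary_noise_sd=0.0,
            )

        def multi_params() -> ShapeParams:
            # tight size spread so each twin clearly exceeds half the
            # larger one's area, and small enough that they stay disjoint
            a = 0.7 * r * rng.uniform(0.95, 1.05)
            b = a * rng.uniform(0.9, 1.0)
            return ShapeParams(
                base_semi_axes=(a, b),
                lobe_order=int(rng.integers(3, 7)),
                lobe_amplitude=eps,
                rotation=rng.uniform(0, 2 * np.pi),
                boundary_noise_sd=0.0,
            )

        if multi:
            offset = np.array([0.85 * r, 0.0])
            add_nucleus(multi_params(), center - offset, is_micro=False)
            add_nucleus(multi_params(), center + offset, is_micro=False)
        else:
            add_nucleus(primary_params(), center, is_micro=False)
        if micro:
            ang = rng.uniform(0, 2 * np.pi)
            mn_r = r * rng.uniform(0.22, 0.28)  # area fraction ~ (0.22..0.28)^2 < 1/9
            at = center + 1.6 * r * np.array([np.cos(ang), np.sin(ang)])
            mp = ShapeParams(
                base_semi_axes=(mn_r, mn_r * rng.uniform(0.85, 1.0)),
                lobe_order=3,
                lobe_amplitude=0.0,
                rotation=0.0,
                boundary_noise_sd=0.0,
            )
            add_nucleus(mp, at, is_micro=True)

        cell_region = np.hypot(xx - center[0], yy - center[1]) <= 2.05 * r
        cell_mask[cell_region & (cell_mask == 0)] = cid
        for coords in focus_coords:
            for fx, fy in coords:
                foci_truth += config.focus_amplitude * np.exp(
                    -((xx - fx) ** 2 + (yy - fy) ** 2) / (2 * config.psf_sigma**2)
                )
        cells.append(
            GroundTruthCell(
                cell_id=cid,
                micronucleated=micro,
                multinucleated=multi,
                dysmorphic=dys,
                nucleus_labels=labels,
                micronucleus_labels=micro_labels,
                contours=contours,
                shape_params=shape_params,
                focus_coords=focus_coords,
            )
        )

    def develop(ideal: np.ndarray, blur: bool = True) -> np.ndarray:
        blurred = ndimage.gaussian_filter(ideal, config.psf_sigma) if blur else ideal
        if config.poisson_scale > 0:
            blurred = (
                rng.poisson(np.clip(blurred, 0, None) * config.poisson_scale)
                / config.poisson_scale
            )
        return blurred + rng.normal(0.0, config.read_noise_sd, blurred.shape)

    nuclear = develop(
        np.where(nucleus_mask > 0, config.foreground, config.background).astype(float)
    )
    actin = develop(
        np.where(cell_mask > 0, 0.55 * config.foreground, config.background).astype(
            float
        )
    )
    # foci are already rendered at PSF width; only noise is added here
    foci_img = develop(config.background + foci_truth, blur=False)
    truth = GroundTruth(cells=cells, nucleus_mask=nucleus_mask, cell_mask=cell_mask)
    return nuclear, actin, foci_img, truth


def gen_borderline_pool(
    target_efc: float,
    n: int,
    rng: np.random.Generator,
    lobe_order: int = 4,
    semi_axes: tuple[float, float] = (30.0, 24.0),
    n_points: int = 256,
    rel_tol: float = 0.01,
) -> list[Contour]:
    """Contours whose EFC ratios bracket a target, via bisection on lobe amplitude.

    Emulates assembling a pool of visually borderline nuclei: each member
    is a lobed contour with randomized orientation whose EFC is driven to
    the target by bisecting the lobe amplitude (EFC is monotone
    decreasing in amplitude for fixed lobe order).  The pool mean EFC
    lands within a few percent of the target.
    """
    if target_efc <= 0:
        raise ValueError("target EFC must be positive (EFC > 0 for finite contours)")
    lo_eps, hi_eps = 1e-4, 0.49

    def efc_at(eps: float, rotation: float) -> tuple[float, Contour]:
        c = gen_nucleus_contour(
            ShapeParams(
                base_semi_axes=semi_axes,
                lobe_order=lobe_order,
                lobe_amplitude=eps,
                rotation=rotation,
            ),
            n_points,
        )
        return contour_efc(c).efc_ratio, c

    pool: list[Contour] = []
    for _ in range(n):
        rot = rng.uniform(0, 2 * np.pi)
        f_lo, _ = efc_at(hi_eps, rot)  # lowest reachable EFC
        f_hi, _ = efc_at(lo_eps, rot)  # highest reachable EFC
        if not f_lo <= target_efc <= f_hi:
            raise ValueError(
                f"target EFC {target_efc:g} unreachable within amplitude bounds "
                f"[{f_lo:.3g}, {f_hi:.3g}]"
            )
        a, b = lo_eps, hi_eps
        best = None
        for _ in range(60):
            mid = 0.5 * (a + b)
            val, cont = efc_at(mid, rot)
            best = cont
            if abs(val - target_efc) <= rel_tol * target_efc:
                break
            if val > target_efc:  # EFC too high -> need more lobing
                a = mid
            else:
                b = mid
        pool.append(best)
    return pool


def gen_toy_loops(
    n_shared: int,
    n_a_unique: int,
    n_b_unique: int,
    chrom_sizes: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
    span_sampler=None,
    anchor_width: int = 5000,
    min_gap: int = 50_000,
) -> dict:
    """Two toy chromatin-loop lists with a known shared/unique partition.

    Returns a dict with DataFrames ``loops_a`` and ``loops_b`` in BEDPE
    column order plus the ledger of which rows are shared, A-unique and
    B-unique.  Anchors are intra-chromosomal, within chromosome bounds,
    and separated so distinct loops never collide under small matching
    tolerances.
    """
    if n_shared + n_a_unique + n_b_unique < 1:
        raise ValueError("need at least one loop")
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 50_000_000, "chr2": 40_000_000, "chr3": 30_000_000}
    if rng is None:
        rng = np.random.default_rng(0)
    if span_sampler is None:
        span_sampler = lambda r: int(r.uniform(80_000, 500_000))

    chroms = list(chrom_sizes)
    used: dict[str, list[int]] = {c: [] for c in chroms}

    def sample_loop() -> dict:
        for _ in range(1000):
            chrom = chroms[rng.integers(len(chroms))]
            span = int(span_sampler(rng))
            size = chrom_sizes[chrom]
            hi = size - span - anchor_width - 1
            if hi <= 0:
                continue
            start1 = int(rng.integers(0, hi))
            mid1 = start1 + anchor_width // 2
            if any(abs(mid1 - u) < min_gap for u in used[chrom]):
                continue
            used[chrom].append(mid1)
            return {
                "chrom1": chrom,
                "start1": start1,
                "end1": start1 + anchor_width,
                "chrom2": chrom,
                "start2": start1 + span,
                "end2": start1 + span + anchor_width,
            }
        raise RuntimeError("could not place loop without anchor collision")

    shared = [sample_loop() for _ in range(n_shared)]
    a_only = [sample_loop() for _ in range(n_a_unique)]
    b_only = [sample_loop() for _ in range(n_b_unique)]
    loops_a = pd.DataFrame(shared + a_only)
    loops_b = pd.DataFrame(shared + b_only)
    return {
        "loops_a": loops_a,
        "loops_b": loops_b,
        "n_shared": n_shared,
        "n_a_unique": n_a_unique,
        "n_b_unique": n_b_unique,
        "per_chrom_a": loops_a["chrom1"].value_counts().to_dict() if len(loops_a) else {},
        "per_chrom_b": loops_b["chrom1"].value_counts().to_dict() if len(loops_b) else {},
    }


def write_bedpe(loops: pd.DataFrame, path) -> None:
    """Write loops as 6-column BEDPE (0-based half-open), tab-separated."""
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    loops[cols].to_csv(path, sep="\t", header=False, index=False)
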