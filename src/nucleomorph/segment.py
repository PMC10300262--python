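"""Image loading, nucleus segmentation and grouping of nuclei into cells.

Supports both whole-field fluorescence images (automatic thresholding and
labelling) and the pre-cropped single-nucleus mode in which each image
file holds one nucleus.  Grayscale conversion of RGB inputs uses fixed
Rec. 709 luminance weights so the pixel's colour information becomes a
brightness measurement without rescaling the intensity range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import feature, filters, measure, segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityImage",
    "LabelMask",
    "NucleusObject",
    "SegmentationParams",
    "load_image",
    "to_grayscale",
    "segment_nuclei",
    "single_nucleus_mode",
    "group_into_cells",
    "label_objects",
]

LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class IntensityImage:
    """2D non-negative intensity image with optional physical calibration."""

    pixels: np.ndarray
    pixel_size_um: float | None = None
    channel_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("IntensityImage requires a 2D array")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError(f"image too small: {px.shape}, need >= 32x32")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LabelMask:
    """Integer label image: 0 = background, 1..n = objects."""

    labels: np.ndarray
    border_labels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 2D integer array")
        object.__setattr__(self, "labels", lab)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def single_object(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class NucleusObject:
    nucleus_id: int
    cell_id: int
    centroid: tuple[float, float]  # (x, y) pixels
    area_px: int
    on_border: bool = False


@dataclass(frozen=True)
class SegmentationParams:
    threshold_method: str = "otsu"  # otsu | a float value
    min_area_px: int = 30  # keeps micronuclei; speckle smaller than this is dropped
    split_touching: bool = False
    presmooth_sigma: float = 1.0  # suppresses JPEG blocking before thresholding
    exclude_border: bool = True
    threshold_value: float | None = None
    watershed_min_distance: int | None = None  # None: from median object radius
    min_contrast_sds: float = 4.0  # fg-bg contrast below this many bg sds -> no objects


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse RGB(A) to luminance (0.2126 R + 0.7152 G + 0.0722 B).

    Idempotent on single-channel inputs; never rescales intensities, so
    8- and 16-bit ranges are preserved as-is.
    """
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return arr[..., :3].astype(float) @ LUMA_WEIGHTS
    if arr.ndim == 3 and arr.shape[-1] == 1:
        return arr[..., 0].astype(float)
    raise ValueError(f"unsupported image shape {arr.shape}")


def load_image(
    path,
    channel_name: str = "",
    pixel_size_um: float | None = None,
    page: int | None = None,
) -> IntensityImage:
    """Read a TIFF/PNG/JPEG image as a grayscale intensity image.

    Multi-page TIFFs: pass ``page`` to pick a channel plane.  Bit depth
    is preserved (a 16-bit image keeps its native intensity range).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                arr = tf.pages[page or 0].asarray() if page is not None else tf.asarray()
                if arr.ndim == 3 and arr.shape[0] < min(arr.shape[1:]):
                    arr = arr[0]  # first page of an unrequested stack
        elif suffix in (".png", ".jpg", ".jpeg"):
            arr = iio.imread(path)
        else:
            raise ValueError(f"unsupported image format {suffix!r}: {path}")
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # noqa: BLE001 - surface reader errors with the filename
        raise OSError(f"could not read image {path}: {exc}") from exc
    return IntensityImage(
        pixels=to_grayscale(arr), pixel_size_um=pixel_size_um, channel_name=channel_name
    )


def _has_contrast(work: np.ndarray, fg: np.ndarray, min_sds: float) -> bool:
    """True if thresholded foreground is genuinely brighter than background."""
    if not fg.any() or fg.all():
        return False
    bg = work[~fg]
    return (work[fg].mean() - bg.mean()) >= min_sds * max(bg.std(), 1e-12)


def _threshold(img: np.ndarray, params: SegmentationParams) -> float:
    if params.threshold_value is not None:
        return float(params.threshold_value)
    if params.threshold_method == "otsu":
        return float(filters.threshold_otsu(img))
    raise ValueError(f"unknown threshold method {params.threshold_method!r}")


def segment_nuclei(
    img: IntensityImage, params: SegmentationParams | None = None
) -> LabelMask:
    """Global-threshold nucleus segmentation with optional watershed split.

    Pipeline: Gaussian pre-smooth, automatic global threshold (Otsu by
    default), hole filling, small-object removal, optional
    distance-transform watershed to split touching nuclei.  Objects that
    touch the image border are recorded in ``border_labels`` so
    morphometry can exclude their partial contours.

    A blank (zero-variance) image yields an empty mask with a warning
    rather than an error.
    """
    params = params or SegmentationParams()
    px = img.pixels
    if px.shape[0] < 64 or px.shape[1] < 64:
        raise ValueError(f"image {px.shape} too small for field segmentation")
    if px.std() == 0:
        warnings.warn("blank image (zero variance): returning empty mask", stacklevel=2)
        return LabelMask(labels=np.zeros(px.shape, dtype=np.int32))
    work = (
        ndimage.gaussian_filter(px, params.presmooth_sigma)
        if params.presmooth_sigma > 0
        else px
    )
    fg = work > _threshold(work, params)
    fg = ndimage.binary_fill_holes(fg)
    if not _has_contrast(work, fg, params.min_contrast_sds):
        warnings.warn(
            "foreground/background contrast too low: returning empty mask",
            stacklevel=2,
        )
        return LabelMask(labels=np.zeros(px.shape, dtype=np.int32))

    if params.split_touching:
        dist = ndimage.gaussian_filter(ndimage.distance_transform_edt(fg), 1.0)
        if params.watershed_min_distance is not None:
            min_dist = params.watershed_min_distance
        else:
            # half the equivalent radius of the median candidate object, so
            # one marker survives per nucleus even inside merged clumps
            comp = measure.label(fg, connectivity=1)
            areas = np.bincount(comp.ravel())[1:]
            areas = areas[areas >= params.min_area_px]
            med_r = np.sqrt(np.median(areas) / np.pi) if len(areas) else 3.0
            min_dist = max(3, int(0.7 * med_r))
        peaks = feature.peak_local_max(
            dist, min_distance=min_dist, labels=fg, exclude_border=False
        )
        markers = np.zeros(px.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        # a small object near a large one can lose its peak to the
        # neighbour's tail inside the suppression window; every
        # component still needs at least one marker or the watershed
        # erases it
        comp = measure.label(fg, connectivity=1)
        marked = np.zeros(comp.max() + 1, dtype=bool)
        marked[comp[tuple(peaks.T)]] = True
        missing = np.nonzero(~marked[1:])[0] + 1
        if len(missing):
            positions = ndimage.maximum_position(dist, comp, missing)
            for k, pos in enumerate(positions):
                markers[pos] = len(peaks) + 1 + k
        labels = segmentation.watershed(-dist, markers, mask=fg)
    else:
        labels = measure.label(fg, connectivity=1)

    # drop objects below the minimum size, then relabel compactly
    counts = np.bincount(labels.ravel())
    too_small = np.nonzero(counts < params.min_area_px)[0]
    labels[np.isin(labels, too_small[too_small > 0])] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    labels = labels.astype(np.int32)

    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    border_labels = frozenset(int(b) for b in border if b > 0)
    return LabelMask(labels=labels, border_labels=border_labels)


def single_nucleus_mode(
    paths,
    params: SegmentationParams | None = None,
    pixel_size_um: float | None = None,
) -> tuple[list[tuple[IntensityImage, LabelMask]], pd.DataFrame]:
    """Process pre-cropped images each containing one dominant nucleus.

    For every readable crop the largest thresholded component is kept as
    the single nucleus; smaller specks are discarded and counted.  Crops
    with no foreground are skipped.  Returns the (image, mask) pairs plus
    a report DataFrame with one row per input path.
    """
    params = params or SegmentationParams(min_area_px=50, exclude_border=False)
    out: list[tuple[IntensityImage, LabelMask]] = []
    rows = []
    for path in paths:
        img = load_image(path, pixel_size_um=pixel_size_um)
        px = img.pixels
        if px.std() == 0:
            rows.append({"path": str(path), "status": "skipped_blank", "n_discarded": 0})
            logger.warning("single-nucleus crop %s is blank; skipped", path)
            continue
        work = (
            ndimage.gaussian_filter(px, params.presmooth_sigma)
            if params.presmooth_sigma > 0
            else px
        )
        fg = ndimage.binary_fill_holes(work > _threshold(work, params))
        if not _has_contrast(work, fg, params.min_contrast_sds):
            rows.append(
                {"path": str(path), "status": "skipped_no_foreground", "n_discarded": 0}
            )
            logger.warning("no usable foreground in %s; skipped", path)
            continue
        lab = measure.label(fg, connectivity=1)
        counts = np.bincount(lab.ravel())
        if len(counts) < 2 or counts[1:].max() < params.min_area_px:
            rows.append(
                {"path": str(path), "status": "skipped_no_foreground", "n_discarded": 0}
            )
            logger.warning("no usable foreground in %s; skipped", path)
            continue
        keep = int(np.argmax(counts[1:]) + 1)
        n_discarded = int((counts[1:] >= 1).sum() - 1)
        single = (lab == keep).astype(np.int32)
        out.append((img, LabelMask(labels=single)))
        rows.append({"path": str(path), "status": "ok", "n_discarded": n_discarded})
        if n_discarded:
            logger.info("%s: discarded %d secondary specks", path, n_discarded)
    return out, pd.DataFrame(rows, columns=["path", "status", "n_discarded"])


def label_objects(mask: LabelMask, cell_ids: dict[int, int] | None = None) -> list[NucleusObject]:
    """Measure centroid and area for every labelled nucleus."""
    props = measure.regionprops(mask.labels)
    objs = []
    for p in props:
        cy, cx = p.centroid
        objs.append(
            NucleusObject(
                nucleus_id=int(p.label),
                cell_id=int(cell_ids.get(p.label, p.label)) if cell_ids else int(p.label),
                centroid=(float(cx), float(cy)),
                area_px=int(p.area),
                on_border=p.label in mask.border_labels,
            )
        )
    return objs


def group_into_cells(
    nuclei: LabelMask,
    actin: IntensityImage | None = None,
    link_radius_px: float = 40.0,
    actin_params: SegmentationParams | None = None,
) -> dict[int, int]:
    """Assign a cell id to every nucleus label.

    With an actin channel, nuclei whose centroids fall in one segmented
    actin (cell) region share a cell id; nuclei outside any actin region
    fall back to distance linking.  Without actin, nuclei are merged by
    single-linkage on centroid distance at ``link_radius_px``: chains
    A-B-C within radius collapse into one cell.
    """
    props = measure.regionprops(nuclei.labels)
    if not props:
        raise ValueError("empty nucleus mask: nothing to group")
    labels = [p.label for p in props]
    centroids = np.array([p.centroid for p in props])  # (row, col)

    parent = {lab: lab for lab in labels}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    assigned = np.zeros(len(labels), dtype=bool)
    if actin is not None:
        ap = actin_params or SegmentationParams(min_area_px=200)
        work = ndimage.gaussian_filter(actin.pixels, ap.presmooth_sigma)
        fg = ndimage.binary_fill_holes(work > _threshold(work, ap))
        regions = measure.label(fg, connectivity=1)
        region_of = {}
        for i, (r, c) in enumerate(centroids):
            reg = int(regions[int(round(r)), int(round(c))])
            if reg > 0:
                region_of.setdefault(reg, []).append(i)
                assigned[i] = True
        for members in region_of.values():
            for i in members[1:]:
                union(labels[members[0]], labels[i])

    # distance-based single linkage for unassigned nuclei (or all, if no actin)
    idx = np.arange(len(labels)) if actin is None else np.nonzero(~assigned)[0]
    for ii, i in enumerate(idx):
        for j in idx[ii + 1 :]:
            if np.hypot(*(centroids[i] - centroids[j])) <= link_radius_px:
                union(labels[i], labels[j])

    roots = sorted({find(lab) for lab in labels})
    compact = {root: k + 1 for k, root in enumerate(roots)}
    return {lab: compact[find(lab)] for lab in labels}
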