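"""Per-cell nuclear phenotype scoring and per-condition summaries.

Cells are scored for three (non-exclusive) chromosomal-instability
phenotypes:

* micronucleated — the cell carries at least one small chromatin body
  near its primary nucleus.  Operationally: area at most ``micro_area_frac``
  (default 1/9, i.e. diameter under one third) of the primary nucleus and
  centroid within ``micro_max_dist_px`` of it.  These cutoffs are
  conventions of this package, surfaced in config and echoed into output
  metadata; scoring of real data in the field is typically visual.
* multinucleated — at least two non-micronucleus nuclei each with area at
  least ``multi_min_frac`` (default 0.5) of the primary, so micronuclei
  never trigger the flag.
* dysmorphic — any constituent primary (non-micro) nucleus has an EFC
  ratio at or below the calibrated dysmorphia threshold.  Micronuclei are
  excluded: they are too small for stable 15-harmonic fits.

Percentages per condition are computed over a single cell denominator and
reported per replicate plus pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MicroMultiParams",
    "NucleusMeasure",
    "CellRecord",
    "PhenotypeSummary",
    "nuclear_area",
    "classify_cell_nuclei",
    "summarize_phenotypes",
]


@dataclass(frozen=True)
class MicroMultiParams:
    micro_area_frac: float = 1.0 / 9.0
    micro_max_dist_px: float = 60.0
    multi_min_frac: float = 0.5


@dataclass(frozen=True)
class NucleusMeasure:
    """Inputs to cell-level classification for one nucleus."""

    nucleus_id: int
    area_px: float
    centroid: tuple[float, float]
    dysmorphic: bool | None = None  # None = not scored (e.g. border or micro)


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    nucleus_ids: tuple[int, ...]  # ordered by area, descending
    micronucleus_ids: tuple[int, ...]
    micronucleus_count: int
    micronucleated: bool
    multinucleated: bool
    dysmorphic: bool
    condition: str = ""
    replicate: int = 0


@dataclass(frozen=True)
class PhenotypeSummary:
    condition: str
    n_cells: int
    percent_micronucleated: float
    percent_multinucleated: float
    percent_dysmorphic: float
    per_replicate: pd.DataFrame = field(repr=False, default=None)


def nuclear_area(
    mask: np.ndarray, pixel_size_um: float | None = None
) -> tuple[int, float | None]:
    """Nuclear area as foreground pixel count, optionally also in um^2."""
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no nucleus to measure")
    um2 = n * pixel_size_um**2 if pixel_size_um is not None else None
    return n, um2


def classify_cell_nuclei(
    cell_id: int,
    nuclei: list[NucleusMeasure],
    params: MicroMultiParams | None = None,
    condition: str = "",
    replicate: int = 0,
) -> CellRecord:
    """Apply the micronucleation / multinucleation rules to one cell.

    The primary nucleus is the largest.  Dysmorphia is inherited from the
    primary (non-micro) nuclei only.
    """
    if not nuclei:
        raise ValueError("a cell must contain at least one nucleus")
    params = params or MicroMultiParams()
    ordered = sorted(nuclei, key=lambda n: (-n.area_px, n.nucleus_id))
    primary = ordered[0]

    micro_ids = []
    for n in ordered[1:]:
        close = (
            np.hypot(
                n.centroid[0] - primary.centroid[0],
                n.centroid[1] - primary.centroid[1],
            )
            <= params.micro_max_dist_px
        )
        if n.area_px <= params.micro_area_frac * primary.area_px and close:
            micro_ids.append(n.nucleus_id)

    non_micro = [n for n in ordered if n.nucleus_id not in micro_ids]
    n_big = sum(
        1 for n in non_micro if n.area_px >= params.multi_min_frac * primary.area_px
    )
    dys = any(n.dysmorphic for n in non_micro if n.dysmorphic is not None)
    return CellRecord(
        cell_id=cell_id,
        nucleus_ids=tuple(n.nucleus_id for n in ordered),
        micronucleus_ids=tuple(micro_ids),
        micronucleus_count=len(micro_ids),
        micronucleated=len(micro_ids) >= 1,
        multinucleated=n_big >= 2,
        dysmorphic=dys,
        condition=condition,
        replicate=replicate,
    )


def cells_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "condition": [r.condition for r in records],
            "replicate": [r.replicate for r in records],
            "n_nuclei": [len(r.nucleus_ids) for r in records],
            "micronucleus_count": [r.micronucleus_count for r in records],
            "micronucleated": [r.micronucleated for r in records],
            "multinucleated": [r.multinucleated for r in records],
            "dysmorphic": [r.dysmorphic for r in records],
        }
    )


def summarize_phenotypes(records: list[CellRecord]) -> list[PhenotypeSummary]:
    """Percentage of cells per condition with each phenotype.

    Categories are not mutually exclusive (one cell can count in
    several).  All three percentages for a condition share the same
    ``n_cells`` denominator; a per-replicate breakdown accompanies the
    pooled value.  Conditions with zero cells simply do not appear.
    """
    if not records:
        raise ValueError("no cell records to summarize")
    df = cells_to_frame(records)
    out: list[PhenotypeSummary] = []
    for cond, grp in df.groupby("condition", sort=True):
        reps = (
            grp.groupby("replicate")
            .agg(
                n_cells=("cell_id", "size"),
                percent_micronucleated=("micronucleated", lambda s: 100.0 * s.mean()),
                percent_multinucleated=("multinucleated", lambda s: 100.0 * s.mean()),
                percent_dysmorphic=("dysmorphic", lambda s: 100.0 * s.mean()),
            )
            .reset_index()
        )
        out.append(
            PhenotypeSummary(
                condition=str(cond),
                n_cells=len(grp),
                percent_micronucleated=100.0 * grp["micronucleated"].mean(),
                percent_multinucleated=100.0 * grp["multinucleated"].mean(),
                percent_dysmorphic=100.0 * grp["dysmorphic"].mean(),
                per_replicate=reps,
            )
        )
    return out
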