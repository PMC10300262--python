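"""End-to-end orchestration: scene -> segmentation -> EFA -> phenotypes -> foci.

`analyze_scene` scores one field of view; `run_pipeline` drives whole
configurations (several conditions x replicates, synthetic or from image
directories), writes per-nucleus / per-cell / summary CSVs and a
machine-readable run manifest carrying the seed, the config hash and the
package version, so a rerun with identical config and inputs is
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .efa import (
    DysmorphiaThreshold,
    calibrate_threshold,
    classify_dysmorphic,
    contour_efc,
    extract_contour,
)
from .foci import FociParams, FociResult, detect_foci, summarize_foci
from .phenotypes import (
    MicroMultiParams,
    NucleusMeasure,
    cells_to_frame,
    classify_cell_nuclei,
    summarize_phenotypes,
)
from .segment import (
    IntensityImage,
    SegmentationParams,
    group_into_cells,
    label_objects,
    segment_nuclei,
    single_nucleus_mode,
)
from .synth import SceneConfig, gen_borderline_pool, render_scene

logger = logging.getLogger(__name__)

__all__ = ["analyze_scene", "score_crops", "run_pipeline", "resolve_threshold"]


def _efc_for_label(mask: np.ndarray, harmonics: int, resample_points: int):
    contour = extract_contour(mask)
    return contour_efc(contour, K=harmonics, resample_points=resample_points)


def analyze_scene(
    nuclear: IntensityImage,
    threshold: DysmorphiaThreshold,
    actin: IntensityImage | None = None,
    foci_channel: IntensityImage | None = None,
    seg_params: SegmentationParams | None = None,
    micro_params: MicroMultiParams | None = None,
    foci_params: FociParams | None = None,
    harmonics: int = 15,
    resample_points: int = 256,
    link_radius_px: float = 40.0,
    condition: str = "",
    replicate: int = 0,
) -> dict:
    """Segment and score one field of view.

    Returns per-nucleus and per-cell DataFrames plus the raw records.
    Touching nuclei are watershed-split by default — multinucleated
    cells hold nuclei that often abut after PSF blur, and an unsplit
    pair masquerades as one large nucleus.  Border-touching nuclei are
    kept in the table but not shape-scored (partial contours bias the
    EFC ratio); micronuclei are likewise not shape-scored.  A nucleus
    that fails contour extraction is skipped with a logged warning
    rather than failing the scene.
    """
    seg_params = seg_params or SegmentationParams(split_touching=True)
    micro_params = micro_params or MicroMultiParams()
    mask = segment_nuclei(nuclear, seg_params)
    if mask.n_objects == 0:
        return {
            "nuclei": pd.DataFrame(),
            "cells": pd.DataFrame(),
            "cell_records": [],
            "foci_results": [],
            "label_mask": mask,
        }
    cell_ids = group_into_cells(mask, actin=actin, link_radius_px=link_radius_px)
    objs = label_objects(mask, cell_ids)

    # provisional cell grouping to identify micronuclei before EFA scoring
    by_cell: dict[int, list] = {}
    for o in objs:
        by_cell.setdefault(o.cell_id, []).append(o)
    micro_labels: set[int] = set()
    for members in by_cell.values():
        prelim = classify_cell_nuclei(
            members[0].cell_id,
            [
                NucleusMeasure(o.nucleus_id, o.area_px, o.centroid)
                for o in members
            ],
            micro_params,
        )
        micro_labels.update(prelim.micronucleus_ids)

    rows = []
    dys_by_label: dict[int, bool | None] = {}
    for o in objs:
        efc = np.nan
        dys: bool | None = None
        scoreable = (
            o.nucleus_id not in micro_labels
            and not (seg_params.exclude_border and o.on_border)
        )
        if scoreable:
            try:
                res = _efc_for_label(
                    mask.single_object(o.nucleus_id), harmonics, resample_points
                )
                efc = res.efc_ratio
                dys = classify_dysmorphic(res, threshold)
            except ValueError as exc:
                logger.warning("nucleus %d skipped in EFA: %s", o.nucleus_id, exc)
        dys_by_label[o.nucleus_id] = dys
        rows.append(
            {
                "nucleus_id": o.nucleus_id,
                "cell_id": o.cell_id,
                "centroid_x": o.centroid[0],
                "centroid_y": o.centroid[1],
                "area_px": o.area_px,
                "border_flag": o.on_border,
                "is_micronucleus": o.nucleus_id in micro_labels,
                "efc_ratio": efc,
                "dysmorphic": dys,
                "threshold_used": threshold.value,
                "condition": condition,
                "replicate": replicate,
            }
        )
    nuclei_df = pd.DataFrame(rows)

    cell_records = []
    for members in by_cell.values():
        measures = [
            NucleusMeasure(
                o.nucleus_id,
                o.area_px,
                o.centroid,
                dysmorphic=dys_by_label[o.nucleus_id],
            )
            for o in members
        ]
        cell_records.append(
            classify_cell_nuclei(
                members[0].cell_id,
                measures,
                micro_params,
                condition=condition,
                replicate=replicate,
            )
        )

    foci_results: list[FociResult] = []
    if foci_channel is not None:
        for o in objs:
            if o.nucleus_id in micro_labels:
                continue
            foci_results.append(
                detect_foci(
                    foci_channel,
                    mask.single_object(o.nucleus_id),
                    foci_params,
                    nucleus_id=o.nucleus_id,
                    condition=condition,
                    replicate=replicate,
                )
            )

    return {
        "nuclei": nuclei_df,
        "cells": cells_to_frame(cell_records),
        "cell_records": cell_records,
        "foci_results": foci_results,
        "label_mask": mask,
    }


def score_crops(
    paths,
    threshold: DysmorphiaThreshold | None = None,
    harmonics: int = 15,
    resample_points: int = 256,
    seg_params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """EFC-score a directory of pre-cropped single-nucleus images."""
    pairs, report = single_nucleus_mode(paths, seg_params)
    ok_paths = report.loc[report["status"] == "ok", "path"].tolist()
    rows = []
    for path, (img, mask) in zip(ok_paths, pairs):
        res = contour_efc(
            extract_contour(mask.labels > 0), K=harmonics, resample_points=resample_points
        )
        rows.append(
            {
                "path": path,
                "area_px": int((mask.labels > 0).sum()),
                "K": harmonics,
                "size_1": res.size_1,
                "sum_sizes_2_K": res.denominator,
                "efc_ratio": res.efc_ratio,
                "dysmorphic": (
                    classify_dysmorphic(res, threshold) if threshold else None
                ),
                "threshold_used": threshold.value if threshold else None,
            }
        )
    return pd.DataFrame(rows)


def resolve_threshold(spec, seed: int = 0) -> DysmorphiaThreshold:
    """Turn a config threshold spec into a DysmorphiaThreshold.

    Accepts a number, ``calibrate:<dir>`` (EFC-score the crops in a
    directory and take their mean), or ``calibrate`` (synthetic
    borderline pool at lobe amplitude 0.12).
    """
    if isinstance(spec, (int, float)):
        return DysmorphiaThreshold(value=float(spec), pool_size=0, provenance="config")
    if isinstance(spec, str) and spec.startswith("calibrate:"):
        pool_dir = Path(spec.split(":", 1)[1])
        paths = sorted(
            p
            for p in pool_dir.iterdir()
            if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff")
        )
        df = score_crops(paths)
        if df.empty:
            raise ValueError(f"no scoreable crops in threshold pool {pool_dir}")
        thr = calibrate_threshold(df["efc_ratio"].tolist())
        return DysmorphiaThreshold(
            value=thr.value, pool_size=thr.pool_size, provenance=f"pool:{pool_dir}"
        )
    if spec == "calibrate":
        rng = np.random.default_rng(seed)
        from .efa import contour_efc as _efc
        from .synth import ShapeParams, gen_nucleus_contour

        ref = gen_nucleus_contour(
            ShapeParams(base_semi_axes=(30.0, 24.0), lobe_order=4, lobe_amplitude=0.12)
        )
        pool = gen_borderline_pool(_efc(ref).efc_ratio, 20, rng)
        thr = calibrate_threshold([_efc(c).efc_ratio for c in pool])
        return DysmorphiaThreshold(
            value=thr.value, pool_size=thr.pool_size, provenance="synthetic borderline pool"
        )
    raise ValueError(f"invalid threshold spec {spec!r}")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full synthetic pipeline described by a config mapping.

    Config schema (validated up front, before any computation)::

        seed: int
        threshold: number | "calibrate" | "calibrate:<pool-dir>"
        conditions:
          <name>:
            replicates: int            # default 1
            scene: {SceneConfig fields}  # n_cells, fractions, foci_rate, ...

    Writes nuclei.csv, cells.csv, phenotype_summary.csv, foci_summary.csv
    (when foci were simulated), summary.txt and manifest.json into
    ``out_dir``.
    """
    if "conditions" not in config or not config["conditions"]:
        raise ValueError("config must define at least one condition")
    seed = int(config.get("seed", 0))
    thr_spec = config.get("threshold", "calibrate")
    scene_field_names = set(SceneConfig.__dataclass_fields__)
    for name, cond in config["conditions"].items():
        unknown = set(cond.get("scene", {})) - scene_field_names
        if unknown:
            raise ValueError(f"condition {name!r}: unknown scene keys {sorted(unknown)}")
        if int(cond.get("replicates", 1)) < 1:
            raise ValueError(f"condition {name!r}: replicates must be >= 1")

    threshold = resolve_threshold(thr_spec, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_nuclei, all_cells, cell_records, foci_results = [], [], [], []
    sub_seed = seed
    for name, cond in config["conditions"].items():
        for rep in range(1, int(cond.get("replicates", 1)) + 1):
            sub_seed += 1
            scene_cfg = SceneConfig(**{**cond.get("scene", {}), "seed": sub_seed})
            nuclear, actin, foci_img, _truth = render_scene(scene_cfg)
            res = analyze_scene(
                IntensityImage(nuclear, channel_name="dna"),
                threshold,
                actin=IntensityImage(actin, channel_name="actin"),
                foci_channel=(
                    IntensityImage(foci_img, channel_name="gh2ax")
                    if scene_cfg.foci_rate > 0
                    else None
                ),
                condition=name,
                replicate=rep,
            )
            all_nuclei.append(res["nuclei"])
            all_cells.append(res["cells"])
            cell_records.extend(res["cell_records"])
            foci_results.extend(res["foci_results"])

    nuclei_df = pd.concat(all_nuclei, ignore_index=True)
    cells_df = pd.concat(all_cells, ignore_index=True)
    nuclei_df.to_csv(out_dir / "nuclei.csv", index=False)
    cells_df.to_csv(out_dir / "cells.csv", index=False)

    summaries = summarize_phenotypes(cell_records)
    summary_df = pd.DataFrame(
        {
            "condition": [s.condition for s in summaries],
            "n_cells": [s.n_cells for s in summaries],
            "percent_micronucleated": [s.percent_micronucleated for s in summaries],
            "percent_multinucleated": [s.percent_multinucleated for s in summaries],
            "percent_dysmorphic": [s.percent_dysmorphic for s in summaries],
        }
    )
    summary_df.to_csv(out_dir / "phenotype_summary.csv", index=False)
    if foci_results:
        summarize_foci(foci_results).to_csv(out_dir / "foci_summary.csv", index=False)

    manifest = {
        "package": "nucleomorph",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "threshold": asdict(threshold),
        "n_conditions": len(config["conditions"]),
        "outputs": sorted(p.name for p in out_dir.glob("*.csv")),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    lines = [
        f"nucleomorph {__version__} run (seed={seed}, config={manifest['config_hash']})",
        f"dysmorphia threshold: {threshold.value:.4g} ({threshold.provenance})",
        "",
        summary_df.to_string(index=False),
    ]
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return {
        "nuclei": nuclei_df,
        "cells": cells_df,
        "phenotype_summary": summary_df,
        "threshold": threshold,
        "manifest": manifest,
    }
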