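"""End-to-end orchestration of the four workflow steps.

execution (read the DICOM slice) -> setting (rescale, window/level,
threshold bands) -> confirmation (rasterize rough ROIs, intersect with
the bands, merge into a disjoint label map) -> extraction (labeled
overlay images, confirmed ROI boundaries, quantification CSV row), plus
the cohort-level evaluation (group summaries with t-tests, two-observer
ICC report).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

from . import imaging_io, preprocess, segmentation, quantify
from .cohort_stats import (MEASURE_NAMES, SubjectRecord, cohort_summary,
                           icc_2_1, two_sample_ttest)
from .config import RunConfig
from .errors import DataError, DegenerateDataError
from .imaging_io import ImageSlice, QuantRecord
from .segmentation import COMPARTMENTS, LabelMap, RoiPolygon

logger = logging.getLogger("bodycomp")


def segment_slice(image: ImageSlice, rois: list[RoiPolygon],
                  config: RunConfig | None = None) -> LabelMap:
    """Setting + confirmation: from slice and rough ROIs to a label map.

    Multiple ROIs sharing a compartment tag are unioned before the
    threshold intersection. Raises if any compartment has no ROI.
    """
    config = config or RunConfig()
    by_tag = {tag: [] for tag in COMPARTMENTS}
    for roi in rois:
        by_tag[roi.compartment].append(roi)
    missing = [tag for tag, lst in by_tag.items() if not lst]
    if missing:
        raise DataError(f"missing rough ROI for compartment(s): {', '.join(missing)}")

    wl = config.window_level()
    intensity = preprocess.apply_rescale(image)
    display = preprocess.window_level(intensity, wl)
    logger.info("setting: window=%g level=%g", wl.window, wl.level)

    finals = {}
    for tag in COMPARTMENTS:
        rough = np.zeros((image.rows, image.cols), dtype=bool)
        for roi in by_tag[tag]:
            rough |= segmentation.rasterize_polygon(roi, image.rows, image.cols)
        band = config.threshold(tag)
        mask = segmentation.finalize_roi(rough, preprocess.threshold_mask(display, band))
        mask = segmentation.filter_small_components(mask, config.min_component_size)
        logger.info("confirmation: %s band=[%d,%d] rough=%d final=%d px",
                    tag, band.low, band.high,
                    int(rough.sum()), int(mask.sum()))
        finals[tag] = mask
    return segmentation.build_label_map(finals["M"], finals["S"], finals["V"])


def quantify_slice(image: ImageSlice, rois: list[RoiPolygon],
                   config: RunConfig | None = None,
                   group: str = "") -> tuple[QuantRecord, LabelMap]:
    """Full in-memory pipeline: label map plus areas/ratios record."""
    config = config or RunConfig()
    label_map = segment_slice(image, rois, config)
    areas = quantify.compute_areas(label_map, image.row_spacing, image.col_spacing)
    ratios = quantify.compute_ratios(areas)
    record = QuantRecord(subject_id=image.subject_id, group=group,
                         areas=areas, ratios=ratios,
                         provenance=config.provenance())
    return record, label_map


def mask_to_polygons(mask: np.ndarray, compartment: str) -> list[RoiPolygon]:
    """Trace a confirmed mask's component boundaries as polygons.

    Approximate: marching-squares contours at the 0.5 level, shifted so
    coordinates align with the pixel-center convention. Components too
    small to yield 3 contour vertices are skipped.
    """
    polys = []
    contours = _skmeasure.find_contours(np.asarray(mask, dtype=float), 0.5)
    for contour in contours:
        if contour.shape[0] < 3:
            continue
        verts = np.column_stack([contour[:, 1] + 0.5, contour[:, 0] + 0.5])
        polys.append(RoiPolygon(vertices=verts, compartment=compartment))
    return polys


def run_quantify(dicom_path, roi_paths, outdir, config: RunConfig | None = None,
                 group: str = "") -> QuantRecord:
    """File-level pipeline: read inputs, write all extraction artifacts.

    Writes into ``outdir``: a labeled overlay image per configured
    format, confirmed-ROI JSON files per compartment component, and a
    one-row quantification CSV.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    image = imaging_io.read_slice(dicom_path)
    logger.info("execution: %s %dx%d px, %gx%g mm", dicom_path,
                image.rows, image.cols, image.row_spacing, image.col_spacing)
    rois = [imaging_io.read_roi(p) for p in roi_paths]
    record, label_map = quantify_slice(image, rois, config, group=group)

    stem = image.subject_id or Path(dicom_path).stem
    for fmt in config.image_formats:
        out = outdir / f"{stem}_labels.{fmt.lower()}"
        imaging_io.write_label_image(label_map, image, out, colors=config.colors)
        logger.info("extraction: wrote %s", out)
    for tag in COMPARTMENTS:
        for i, poly in enumerate(mask_to_polygons(label_map.mask(tag), tag)):
            out = outdir / f"{stem}_{tag}_confirmed_{i:02d}.json"
            imaging_io.write_roi(poly, out, image_shape=label_map.shape)
    csv_path = outdir / f"{stem}_quant.csv"
    imaging_io.write_quant_csv([record], csv_path)
    logger.info("extraction: wrote %s", csv_path)
    return record


def _records_from_csv(path) -> pd.DataFrame:
    recs = imaging_io.read_quant_csv(path)
    rows = []
    for r in recs:
        row = {"subject_id": r.subject_id, "group": r.group,
               "MA": r.areas.MA, "SA": r.areas.SA, "VA": r.areas.VA}
        row.update(r.ratios.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_cohort(group_a_csv, group_b_csv) -> pd.DataFrame:
    """Two-group comparison: per-measure mean ± SD and t-test p-value.

    Measures whose variance structure is degenerate (e.g. zero pooled
    variance) are reported with the error message instead of a p-value.
    """
    df_a = _records_from_csv(group_a_csv)
    df_b = _records_from_csv(group_b_csv)
    if len(df_a) < 2 or len(df_b) < 2:
        raise DataError("each group needs >= 2 subjects")
    rows = []
    for measure in MEASURE_NAMES:
        a = df_a[measure].dropna().to_numpy()
        b = df_b[measure].dropna().to_numpy()
        row = {"measure": measure,
               "mean_a": float(np.mean(a)), "sd_a": float(np.std(a, ddof=1)),
               "mean_b": float(np.mean(b)), "sd_b": float(np.std(b, ddof=1))}
        try:
            res = two_sample_ttest(a, b)
            row.update(t=res.t, df=res.df, p=res.p, error="")
        except DegenerateDataError as exc:
            row.update(t=float("nan"), df=float("nan"), p=float("nan"),
                       error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")


def run_icc(observer_a_csv, observer_b_csv) -> pd.DataFrame:
    """Two-observer reliability: per-measure ICC(2,1) with 95% CI and band.

    Subjects are matched by subject_id; both CSVs must cover the same
    subjects.
    """
    df_a = _records_from_csv(observer_a_csv).set_index("subject_id").sort_index()
    df_b = _records_from_csv(observer_b_csv).set_index("subject_id").sort_index()
    if not df_a.index.equals(df_b.index):
        raise DataError("observer CSVs do not cover the same subject_ids")
    rows = []
    for measure in MEASURE_NAMES:
        pair = np.column_stack([df_a[measure].to_numpy(),
                                df_b[measure].to_numpy()])
        pair = pair[~np.isnan(pair).any(axis=1)]
        res = icc_2_1(pair)
        rows.append({"measure": measure, "icc": res.icc,
                     "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
                     "p": res.p, "category": res.category,
                     "n": res.n_subjects})
    return pd.DataFrame(rows).set_index("measure")
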