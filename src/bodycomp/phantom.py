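"""Synthetic abdominal phantom generation.

Emulates a single T1-weighted L3-level slice as nested elliptical
compartments on a 512×512 grid with 0.74×0.74 mm pixels: a bright
subcutaneous-fat annulus just under the body outline, an intermediate-
intensity muscle ring inside it, and bright visceral-fat ellipses
scattered in the dark central cavity. Fat appears brighter than muscle,
muscle brighter than background — the T1 contrast ordering — and
subcutaneous and visceral fat share one intensity band, so the pipeline
can only separate them through ROI membership, exactly as in the manual
workflow the package automates.

Every output (pixels, ground-truth label map, analytic areas, rough
ROIs) is fully determined by the spec and its seed. Ground truth labels
each pixel by whether its center lies in the analytic region; analytic
areas come from closed-form ellipse/annulus formulas, so segmentation
accuracy can be scored without any manual reference.

The module also simulates cohorts (per-group Gaussian areas matching
published group means/SDs) and two-observer rating pairs with known
variance components, so the evaluation statistics are testable
end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort_stats import SubjectRecord, classify_group
from .errors import ConfigError
from .imaging_io import ImageSlice
from .quantify import CompartmentAreas, compute_ratios
from .segmentation import (BACKGROUND, MUSCLE, SUBCUT_FAT, VISCERAL_FAT,
                           LabelMap, RoiPolygon)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity description of a synthetic L3 slice.

    Default geometry: body outline ellipse with semi-axes 200×150 px
    centered on a 512×512 grid, a 28 px subcutaneous-fat annulus, a
    22 px muscle ring, and three visceral-fat ellipses in the central
    cavity. Intensity means (8-bit scale) follow the T1 ordering
    fat > muscle > background, separated by 10 noise SDs at the default
    noise level so threshold bands are unambiguous.
    """

    rows: int = 512
    cols: int = 512
    row_spacing: float = 0.74
    col_spacing: float = 0.74
    center: tuple[float, float] = (256.0, 256.0)  # (cx, cy) in pixels
    body_axes: tuple[float, float] = (200.0, 150.0)  # (a, b) semi-axes, px
    subcut_thickness: float = 28.0  # px
    muscle_thickness: float = 22.0  # px
    visceral_ellipses: tuple = (
        ((216.0, 256.0), (30.0, 22.0)),
        ((296.0, 256.0), (28.0, 20.0)),
        ((256.0, 216.0), (25.0, 18.0)),
    )  # ((cx, cy), (a, b)) each
    fat_mean: float = 200.0
    muscle_mean: float = 100.0
    background_mean: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        a, b = self.body_axes
        inner = min(a, b) - self.subcut_thickness - self.muscle_thickness
        if self.subcut_thickness <= 0 or self.muscle_thickness <= 0 or inner <= 0:
            raise ConfigError("compartment thicknesses must be positive and nested")
        for m in (self.fat_mean, self.muscle_mean, self.background_mean):
            if not 0 <= m <= 255:
                raise ConfigError("intensity means must lie in [0, 255]")
        if not self.fat_mean > self.muscle_mean > self.background_mean:
            raise ConfigError(
                "T1 contrast ordering requires fat > muscle > background means")
        if self.noise_sd < 0:
            raise ConfigError("noise SD must be >= 0")

    @property
    def sub_inner_axes(self) -> tuple[float, float]:
        """Inner boundary of the subcutaneous annulus (= outer muscle boundary)."""
        a, b = self.body_axes
        return (a - self.subcut_thickness, b - self.subcut_thickness)

    @property
    def muscle_inner_axes(self) -> tuple[float, float]:
        """Inner muscle boundary (= visceral cavity outline)."""
        a, b = self.sub_inner_axes
        return (a - self.muscle_thickness, b - self.muscle_thickness)


@dataclass
class PhantomResult:
    """Everything a pipeline run can be scored against."""

    image: ImageSlice
    truth: LabelMap
    analytic_areas: CompartmentAreas
    rough_rois: list  # RoiPolygon for M, S, V (V may repeat)
    spec: PhantomSpec


def _inside_ellipse(px, py, center, axes):
    cx, cy = center
    a, b = axes
    return ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 <= 1.0


def ellipse_polygon(center, axes, n: int = 256, compartment: str = "M") -> RoiPolygon:
    """Polygon inscribed in an ellipse, sampled at n uniform angles."""
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    cx, cy = center
    a, b = axes
    verts = np.column_stack([cx + a * np.cos(theta), cy + b * np.sin(theta)])
    return RoiPolygon(vertices=verts, compartment=compartment)


def annulus_polygon(center, outer_axes, inner_axes, n: int = 256,
                    slit_halfwidth: float = 0.05,
                    compartment: str = "S") -> RoiPolygon:
    """Keyhole polygon covering an elliptical annulus.

    A simple (hole-free) polygon cannot represent an annulus, so the
    outer and inner boundaries are joined through a radial slit of
    half-width ``slit_halfwidth`` px on the +x side. The slit is placed
    at the ellipse center's y ordinate; with sub-0.5 px half-width it
    excludes no pixel centers (centers sit at half-integer coordinates),
    so rasterization of the keyhole equals rasterization of the ideal
    annulus.
    """
    cx, cy = center
    ao, bo = outer_axes
    ai, bi = inner_axes
    if not (ao > ai > 0 and bo > bi > 0):
        raise ConfigError("outer axes must strictly contain inner axes")
    d_out = math.asin(min(slit_halfwidth / bo, 1.0))
    d_in = math.asin(min(slit_halfwidth / bi, 1.0))
    outer_t = np.linspace(d_out, 2 * math.pi - d_out, n)
    inner_t = np.linspace(2 * math.pi - d_in, d_in, n)  # reverse orientation
    outer = np.column_stack([cx + ao * np.cos(outer_t), cy + bo * np.sin(outer_t)])
    inner = np.column_stack([cx + ai * np.cos(inner_t), cy + bi * np.sin(inner_t)])
    return RoiPolygon(vertices=np.vstack([outer, inner]), compartment=compartment)


def _check_geometry(spec: PhantomSpec) -> None:
    """Reject visceral ellipses that overlap each other or leave the cavity."""
    cav = spec.muscle_inner_axes
    theta = np.linspace(0, 2 * math.pi, 360, endpoint=False)
    for (c, ax) in spec.visceral_ellipses:
        bx = c[0] + ax[0] * np.cos(theta)
        by = c[1] + ax[1] * np.sin(theta)
        if not np.all(_inside_ellipse(bx, by, spec.center, cav)):
            raise ConfigError(
                f"visceral ellipse at {c} extends outside the visceral cavity")
    for i, (c1, ax1) in enumerate(spec.visceral_ellipses):
        for c2, ax2 in spec.visceral_ellipses[i + 1:]:
            bx = c1[0] + ax1[0] * np.cos(theta)
            by = c1[1] + ax1[1] * np.sin(theta)
            if np.any(_inside_ellipse(bx, by, c2, ax2)):
                raise ConfigError(
                    f"visceral ellipses at {c1} and {c2} overlap")


def make_phantom_slice(spec: PhantomSpec | None = None) -> PhantomResult:
    """Generate one synthetic slice with ground truth and rough ROIs.

    The rough polygons are dilated supersets of their true regions
    (muscle: a padded ellipse over the whole muscle disk; subcutaneous
    fat: a padded keyhole annulus; visceral fat: a slightly shrunk
    cavity ellipse), so the confirmation step must rely on the intensity
    thresholds to recover exact compartments — the property the phantom
    exists to exercise.
    """
    spec = spec or PhantomSpec()
    _check_geometry(spec)
    cx, cy = spec.center
    a0, b0 = spec.body_axes
    a1, b1 = spec.sub_inner_axes
    a2, b2 = spec.muscle_inner_axes

    jj, ii = np.meshgrid(np.arange(spec.cols), np.arange(spec.rows))
    px = jj + 0.5
    py = ii + 0.5

    in_body = _inside_ellipse(px, py, spec.center, (a0, b0))
    in_sub_inner = _inside_ellipse(px, py, spec.center, (a1, b1))
    in_musc_inner = _inside_ellipse(px, py, spec.center, (a2, b2))
    sub_mask = in_body & ~in_sub_inner
    musc_mask = in_sub_inner & ~in_musc_inner
    visc_mask = np.zeros_like(in_body)
    for (c, ax) in spec.visceral_ellipses:
        visc_mask |= _inside_ellipse(px, py, c, ax)

    labels = np.full((spec.rows, spec.cols), BACKGROUND, dtype=np.uint8)
    labels[sub_mask] = SUBCUT_FAT
    labels[musc_mask] = MUSCLE
    labels[visc_mask] = VISCERAL_FAT
    truth = LabelMap(labels)

    intensity = np.full((spec.rows, spec.cols), spec.background_mean)
    intensity[sub_mask | visc_mask] = spec.fat_mean
    intensity[musc_mask] = spec.muscle_mean
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, intensity.shape)
    pixels = np.clip(np.floor(intensity + 0.5), 0, 255).astype(np.uint8)

    image = ImageSlice(
        pixels=pixels, row_spacing=spec.row_spacing, col_spacing=spec.col_spacing,
        subject_id=f"phantom-{spec.seed}", bit_depth=8,
    )

    pixel_area = spec.row_spacing * spec.col_spacing
    va = sum(math.pi * ax[0] * ax[1] for _, ax in spec.visceral_ellipses)
    analytic = CompartmentAreas(
        MA=math.pi * (a1 * b1 - a2 * b2) * pixel_area,
        SA=math.pi * (a0 * b0 - a1 * b1) * pixel_area,
        VA=va * pixel_area,
    )

    # rough ROIs: dilated supersets; pad stays below the ring thicknesses
    pad = min(spec.subcut_thickness, spec.muscle_thickness) / 3.0
    roi_m = ellipse_polygon(spec.center, (a1 + pad, b1 + pad), compartment="M")
    roi_s = annulus_polygon(spec.center, (a0 + pad, b0 + pad),
                            (a1 - pad, b1 - pad), compartment="S")
    roi_v = ellipse_polygon(spec.center, (a2 - 1.0, b2 - 1.0), compartment="V")

    return PhantomResult(image=image, truth=truth, analytic_areas=analytic,
                         rough_rois=[roi_m, roi_s, roi_v], spec=spec)


@dataclass(frozen=True)
class CohortGroupParams:
    """Gaussian generators for one group's areas and anthropometrics."""

    label: str
    ma: tuple[float, float]  # (mean, sd) mm²
    sa: tuple[float, float]
    va: tuple[float, float]
    bmi: tuple[float, float]  # kg/m²
    bmi_range: tuple[float, float]
    alt: tuple[float, float]  # IU/L
    alt_range: tuple[float, float]


#: published group-level area and anthropometric distributions used as
#: simulation defaults: sarcopenic obesity vs healthy controls, n=30 each
SARCOPENIC_PARAMS = CohortGroupParams(
    label="sarcopenic-obesity",
    ma=(14384.9, 3684.5), sa=(22337.2, 5588.8), va=(16224.6, 6439.1),
    bmi=(29.4, 2.5), bmi_range=(25.0, math.inf),
    alt=(121.8, 90.4), alt_range=(35.0, math.inf),
)
HEALTHY_PARAMS = CohortGroupParams(
    label="healthy",
    ma=(15492.2, 6479.0), sa=(10489.7, 5222.7), va=(12211.2, 5132.4),
    bmi=(21.5, 1.6), bmi_range=(18.0, 23.0),
    alt=(34.7, 42.6), alt_range=(0.0, 34.999),
)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled Gaussian restricted to [lo, hi]; deterministic per rng."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def make_cohort(n_per_group: int = 30,
                group_params: tuple[CohortGroupParams, ...] = (
                    SARCOPENIC_PARAMS, HEALTHY_PARAMS),
                seed: int = 0) -> list[SubjectRecord]:
    """Simulate a two-group cohort of per-subject areas and anthropometrics.

    Areas are Gaussian draws (truncated at 0) with the group means/SDs;
    BMI and ALT are drawn within the defining band of each group, so
    :func:`classify_group` reproduces the intended labels exactly.
    """
    rng = np.random.default_rng(seed)
    records = []
    for params in group_params:
        ma = np.maximum(rng.normal(*params.ma, n_per_group), 0.0)
        sa = np.maximum(rng.normal(*params.sa, n_per_group), 0.0)
        va = np.maximum(rng.normal(*params.va, n_per_group), 0.0)
        bmi = _truncated_normal(rng, *params.bmi, *params.bmi_range, n_per_group)
        alt = _truncated_normal(rng, *params.alt, *params.alt_range, n_per_group)
        for i in range(n_per_group):
            areas = CompartmentAreas(MA=float(ma[i]), SA=float(sa[i]),
                                     VA=float(va[i]))
            records.append(SubjectRecord(
                subject_id=f"{params.label}-{i:03d}",
                bmi=float(bmi[i]), alt=float(alt[i]),
                group=classify_group(float(bmi[i]), float(alt[i])),
                areas=areas, ratios=compute_ratios(areas),
            ))
    return records


def make_rater_pair(true_values, rater_offsets=(0.0, 0.0), error_sd: float = 0.0,
                    seed: int = 0) -> np.ndarray:
    """Simulate an (n × k) two-way rating table with known components.

    rating[subject, rater] = truth + rater offset + iid N(0, error_sd²).
    With zero offsets the population ICC(2,1) is
    var(truth) / (var(truth) + error_sd²).
    """
    if error_sd < 0:
        raise ConfigError("error SD must be >= 0")
    truth = np.asarray(true_values, dtype=np.float64)
    offsets = np.asarray(rater_offsets, dtype=np.float64)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, error_sd, size=(truth.size, offsets.size)) \
        if error_sd > 0 else np.zeros((truth.size, offsets.size))
    return truth[:, None] + offsets[None, :] + noise
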