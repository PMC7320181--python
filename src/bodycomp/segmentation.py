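"""ROI confirmation: rasterize rough polygons and intersect with threshold masks.

The workflow is deliberately semi-automatic: an operator draws one rough
polygon per compartment (muscle M, subcutaneous fat S, visceral fat V),
and the final compartment region is the set of pixels that are both
inside the rough polygon and inside the compartment's intensity band.
Subcutaneous and visceral fat share an intensity band on T1-weighted
images, so their separation is carried entirely by the rough polygons.

Rasterization contract: a pixel (i, j) belongs to a polygon iff its
center (j + 0.5, i + 0.5) is inside under the even-odd rule; a center
exactly on an edge resolves by the half-open convention of the crossing
test (lower/left edges count as inside), which is deterministic and
matched exactly by the brute-force oracle used in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import DataError, InvalidPolygonError

COMPARTMENTS = ("M", "S", "V")

#: integer codes used in LabelMap arrays
BACKGROUND, MUSCLE, SUBCUT_FAT, VISCERAL_FAT = 0, 1, 2, 3
LABEL_CODES = {"M": MUSCLE, "S": SUBCUT_FAT, "V": VISCERAL_FAT}


@dataclass(frozen=True)
class RoiPolygon:
    """A closed rough compartment boundary in continuous pixel coordinates.

    ``vertices`` is an (n, 2) float array of (x, y) = (col, row) points,
    implicitly closed; ``compartment`` is one of M, S, V.
    """

    vertices: np.ndarray
    compartment: str

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidPolygonError(
                f"polygon needs >= 3 (x, y) vertices, got shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)
        if self.compartment not in COMPARTMENTS:
            raise DataError(
                f"unknown compartment tag {self.compartment!r}; expected one of "
                f"{'/'.join(COMPARTMENTS)}"
            )

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def validate_simple(self) -> None:
        """Raise InvalidPolygonError if self-intersecting or of zero area."""
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidPolygonError(
                f"polygon for compartment {self.compartment} is self-intersecting "
                "or has non-positive area"
            )


@dataclass
class LabelMap:
    """Per-pixel compartment assignment; one label per pixel by construction."""

    labels: np.ndarray  # uint8, codes BACKGROUND/MUSCLE/SUBCUT_FAT/VISCERAL_FAT

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise DataError("label map must be a 2-D grid")

    @property
    def shape(self):
        return self.labels.shape

    def mask(self, compartment: str) -> np.ndarray:
        return self.labels == LABEL_CODES[compartment]

    def counts(self) -> dict:
        """Pixel count per compartment tag."""
        return {c: int(np.count_nonzero(self.labels == code))
                for c, code in LABEL_CODES.items()}


def rasterize_polygon(polygon: RoiPolygon, rows: int, cols: int) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    Even-odd (crossing-number parity) rule evaluated at every pixel
    center (j + 0.5, i + 0.5). Vectorized over the polygon's bounding
    box; identical by construction to a per-pixel crossing test.
    """
    if rows <= 0 or cols <= 0:
        raise DataError(f"grid dimensions must be positive, got {rows}x{cols}")
    polygon.validate_simple()
    verts = polygon.vertices
    mask = np.zeros((rows, cols), dtype=bool)

    # restrict work to the bounding box of the polygon
    j0 = max(int(np.floor(verts[:, 0].min() - 0.5)), 0)
    j1 = min(int(np.ceil(verts[:, 0].max() - 0.5)) + 1, cols)
    i0 = max(int(np.floor(verts[:, 1].min() - 0.5)), 0)
    i1 = min(int(np.ceil(verts[:, 1].max() - 0.5)) + 1, rows)
    if j0 >= j1 or i0 >= i1:
        return mask

    px = np.arange(j0, j1, dtype=np.float64) + 0.5  # (w,)
    py = np.arange(i0, i1, dtype=np.float64) + 0.5  # (h,)
    PX = px[np.newaxis, :]
    PY = py[:, np.newaxis]
    inside = np.zeros((i1 - i0, j1 - j0), dtype=bool)

    x1s, y1s = verts[:, 0], verts[:, 1]
    x2s, y2s = np.roll(x1s, -1), np.roll(y1s, -1)
    for x1, y1, x2, y2 in zip(x1s, y1s, x2s, y2s):
        if y1 == y2:  # horizontal edges never cross a scan ray
            continue
        crosses = (y1 > PY) != (y2 > PY)
        with np.errstate(invalid="ignore"):
            xint = x1 + (PY - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (PX < xint)

    mask[i0:i1, j0:j1] = inside
    return mask


def point_in_polygon(x: float, y: float, vertices: np.ndarray) -> bool:
    """Scalar even-odd containment test for a single point.

    Reference predicate defining the rasterization contract; shares the
    crossing rule (and therefore the edge tie-break) with
    :func:`rasterize_polygon` but none of its vectorized code path.
    """
    verts = np.asarray(vertices, dtype=np.float64)
    n = verts.shape[0]
    inside = False
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        if y1 == y2:
            continue
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def finalize_roi(rough_mask: np.ndarray, thresh_mask: np.ndarray) -> np.ndarray:
    """Final compartment region: pixels inside both the rough ROI and the band.

    The confirmation step of the workflow — the overlaid area between the
    roughly drawn ROI and the thresholded region, i.e. the logical AND.
    """
    rough = np.asarray(rough_mask, dtype=bool)
    thresh = np.asarray(thresh_mask, dtype=bool)
    if rough.shape != thresh.shape:
        raise DataError(
            f"mask dimensions differ: rough {rough.shape} vs threshold {thresh.shape}"
        )
    return rough & thresh


def filter_small_components(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 4-connected components smaller than ``min_size`` pixels.

    Optional cleanup, off by default (min_size <= 1 returns the mask
    unchanged); the core workflow applies no morphological filtering.
    """
    if min_size <= 1:
        return np.asarray(mask, dtype=bool)
    from scipy import ndimage

    lab, n = ndimage.label(np.asarray(mask, dtype=bool))
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(lab, keep)


def build_label_map(m_mask: np.ndarray, s_mask: np.ndarray,
                    v_mask: np.ndarray) -> LabelMap:
    """Merge final compartment masks into one disjoint label map.

    Pixels claimed by more than one compartment resolve by fixed priority
    M > S > V (muscle is the diagnostic target; double counting would
    corrupt the ratio indexes); a warning reports the overlap pixel count.
    """
    m = np.asarray(m_mask, dtype=bool)
    s = np.asarray(s_mask, dtype=bool)
    v = np.asarray(v_mask, dtype=bool)
    if not (m.shape == s.shape == v.shape):
        raise DataError("compartment masks must share dimensions")

    n_overlap = int(np.count_nonzero((m & s) | (m & v) | (s & v)))
    if n_overlap:
        warnings.warn(
            f"{n_overlap} pixel(s) claimed by multiple compartments; "
            "resolved by priority M > S > V",
            stacklevel=2,
        )
    labels = np.zeros(m.shape, dtype=np.uint8)
    labels[v] = VISCERAL_FAT
    labels[s] = SUBCUT_FAT
    labels[m] = MUSCLE
    return LabelMap(labels)
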