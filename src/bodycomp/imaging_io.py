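"""File I/O: DICOM slices, JSON ROI polygons, labeled overlay images, CSV tables.

A single 2-D DICOM slice is the unit of processing. On load the stored
values are normalized to a single intensity convention — higher value =
brighter — by inverting MONOCHROME1 images, so every downstream
threshold can assume bright fat on T1-weighted images.

The native ROI format is a small JSON schema (an ImageJ-independent
polygon representation)::

    {"type": "bodycomp-roi", "version": 1, "compartment": "M",
     "vertices": [[x, y], ...], "image_rows": 512, "image_cols": 512}

Vertices are continuous (col, row) = (x, y) pixel coordinates,
implicitly closed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from PIL import Image

from .errors import DataError, FormatError, InvalidPolygonError
from .quantify import CompartmentAreas, RatioSet
from .segmentation import LABEL_CODES, LabelMap, RoiPolygon

#: default overlay colors per compartment (RGB)
DEFAULT_COLORS = {"M": (255, 0, 0), "S": (255, 255, 0), "V": (0, 0, 255)}

_IMAGE_FORMATS = {".tif": "TIFF", ".tiff": "TIFF", ".png": "PNG",
                  ".jpg": "JPEG", ".jpeg": "JPEG", ".bmp": "BMP"}

# Secondary Capture Image Storage
_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"


@dataclass
class ImageSlice:
    """One 2-D MR slice with spacing and rescale metadata.

    ``pixels`` are stored integer values, already normalized so that
    higher = brighter; ``row_spacing``/``col_spacing`` are mm per pixel.
    """

    pixels: np.ndarray
    row_spacing: float
    col_spacing: float
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    photometric: str = "MONOCHROME2"
    subject_id: str = ""
    bit_depth: int = 8

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DataError("pixels must be a non-empty 2-D grid")
        if self.row_spacing <= 0 or self.col_spacing <= 0:
            raise DataError(
                f"pixel spacing must be positive mm, got "
                f"{self.row_spacing} x {self.col_spacing}"
            )
        if self.bit_depth not in (8, 12, 16):
            raise DataError(f"bit depth must be 8, 12 or 16, got {self.bit_depth}")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class QuantRecord:
    """One subject's quantification row: areas, ratios and provenance."""

    subject_id: str
    group: str
    areas: CompartmentAreas
    ratios: RatioSet
    provenance: dict = field(default_factory=dict)


def read_slice(path) -> ImageSlice:
    """Read a single-frame DICOM file into an ImageSlice.

    Pixel spacing comes from PixelSpacing (row, col order); rescale
    slope/intercept default to 1/0 when absent. MONOCHROME1 images are
    inverted on load (v -> 2**bits_stored - 1 - v) so that higher value
    = brighter throughout the pipeline.
    """
    ds = pydicom.dcmread(str(path), force=True)
    if "PixelData" not in ds:
        raise FormatError(f"{path}: no PixelData; not an image DICOM")
    if "PixelSpacing" not in ds:
        raise FormatError(
            f"{path}: missing PixelSpacing (0028,0030); "
            "areas in mm² cannot be computed without it"
        )
    try:
        pixels = ds.pixel_array
    except Exception as exc:  # undecodable transfer syntax etc.
        raise FormatError(f"{path}: cannot decode pixel data: {exc}") from exc
    if pixels.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame 2-D image")

    bits_stored = int(getattr(ds, "BitsStored", 8 * pixels.dtype.itemsize))
    bit_depth = bits_stored if bits_stored in (8, 12, 16) else (
        8 if bits_stored <= 8 else (12 if bits_stored <= 12 else 16))
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric == "MONOCHROME1":
        pixels = (2 ** bits_stored - 1) - pixels

    spacing = [float(v) for v in ds.PixelSpacing]
    return ImageSlice(
        pixels=pixels,
        row_spacing=spacing[0],
        col_spacing=spacing[1],
        rescale_slope=float(getattr(ds, "RescaleSlope", 1.0)),
        rescale_intercept=float(getattr(ds, "RescaleIntercept", 0.0)),
        photometric=photometric,
        subject_id=str(getattr(ds, "PatientID", "") or Path(path).stem),
        bit_depth=bit_depth,
    )


def write_slice(img: ImageSlice, path) -> None:
    """Write an ImageSlice as a secondary-capture DICOM file.

    Pixels are written as they are held in memory (bright = high), so a
    write/read round trip is the identity regardless of the photometric
    interpretation of the original source.
    """
    bits_alloc = 8 if img.bit_depth == 8 else 16
    dtype = np.uint8 if bits_alloc == 8 else np.uint16
    pixels = np.ascontiguousarray(img.pixels, dtype=dtype)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _SC_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _SC_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.PatientID = img.subject_id
    ds.Rows, ds.Columns = img.rows, img.cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = bits_alloc
    ds.BitsStored = img.bit_depth
    ds.HighBit = img.bit_depth - 1
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [f"{img.row_spacing:g}", f"{img.col_spacing:g}"]
    ds.RescaleSlope = f"{img.rescale_slope:g}"
    ds.RescaleIntercept = f"{img.rescale_intercept:g}"
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def render_grayscale(img: ImageSlice) -> np.ndarray:
    """8-bit grayscale rendering of the stored pixels (full-range scaling)."""
    maxval = 2 ** img.bit_depth - 1
    scaled = img.pixels.astype(np.float64) * (255.0 / maxval)
    return np.floor(scaled + 0.5).astype(np.uint8)


def write_label_image(label_map: LabelMap, base_image: ImageSlice, path,
                      fmt: str | None = None, colors: dict | None = None) -> None:
    """Write the base image with compartments color-overlaid.

    Labeled pixels are painted in solid compartment colors over the
    grayscale base render, so on lossless formats (TIFF/PNG/BMP) the
    per-color pixel counts equal the compartment pixel counts exactly.
    Format is inferred from the extension unless ``fmt`` is given.
    """
    if label_map.shape != (base_image.rows, base_image.cols):
        raise DataError(
            f"label map {label_map.shape} does not match image "
            f"{(base_image.rows, base_image.cols)}"
        )
    if fmt is None:
        ext = Path(path).suffix.lower()
        if ext not in _IMAGE_FORMATS:
            raise DataError(
                f"unsupported image extension {ext!r}; supported: "
                + ", ".join(sorted(set(_IMAGE_FORMATS))))
        fmt = _IMAGE_FORMATS[ext]
    else:
        fmt = fmt.upper()
        if fmt == "TIF":
            fmt = "TIFF"
        if fmt == "JPG":
            fmt = "JPEG"
        if fmt not in set(_IMAGE_FORMATS.values()):
            raise DataError(
                f"unsupported image format {fmt!r}; supported: "
                + ", ".join(sorted(set(_IMAGE_FORMATS.values()))))

    colors = {**DEFAULT_COLORS, **(colors or {})}
    gray = render_grayscale(base_image)
    rgb = np.stack([gray] * 3, axis=-1)
    for tag, code in LABEL_CODES.items():
        rgb[label_map.labels == code] = colors[tag]
    Image.fromarray(rgb, mode="RGB").save(str(path), format=fmt)


def read_roi(path) -> RoiPolygon:
    """Read a polygon ROI from the JSON schema documented in this module."""
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(obj, dict) or obj.get("type") != "bodycomp-roi":
        raise FormatError(f"{path}: not a bodycomp-roi JSON file")
    verts = obj.get("vertices", [])
    if len(verts) < 3:
        raise InvalidPolygonError(
            f"{path}: polygon needs >= 3 vertices, got {len(verts)}")
    return RoiPolygon(vertices=np.asarray(verts, dtype=np.float64),
                      compartment=obj.get("compartment", ""))


def write_roi(polygon: RoiPolygon, path,
              image_shape: tuple[int, int] | None = None) -> None:
    """Write a polygon ROI as JSON; write-then-read is vertex-identical."""
    obj = {
        "type": "bodycomp-roi",
        "version": 1,
        "compartment": polygon.compartment,
        "vertices": [[float(x), float(y)] for x, y in polygon.vertices],
    }
    if image_shape is not None:
        obj["image_rows"], obj["image_cols"] = int(image_shape[0]), int(image_shape[1])
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


#: fixed CSV header for quantification tables
QUANT_CSV_FIELDS = (
    "subject_id", "group", "MA_mm2", "SA_mm2", "VA_mm2",
    "MA_SA", "MA_VA", "MA_SAVA",
    "window", "level",
    "thr_muscle_low", "thr_muscle_high", "thr_fat_low", "thr_fat_high",
)


def write_quant_csv(records: list[QuantRecord], path) -> None:
    """Write quantification records as an RFC-4180 CSV.

    Areas carry 1 decimal, ratios 6 decimals (full precision lives in
    the CSV; printed summaries round to 1 decimal elsewhere). Undefined
    ratios are written as empty fields.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=QUANT_CSV_FIELDS)
        writer.writeheader()
        for rec in records:
            prov = rec.provenance
            row = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "MA_mm2": f"{rec.areas.MA:.1f}",
                "SA_mm2": f"{rec.areas.SA:.1f}",
                "VA_mm2": f"{rec.areas.VA:.1f}",
            }
            for name, value in rec.ratios.as_dict().items():
                row[name] = "" if value is None else f"{value:.6f}"
            for key in QUANT_CSV_FIELDS[8:]:
                row[key] = prov.get(key, "")
            writer.writerow(row)


def read_quant_csv(path) -> list[QuantRecord]:
    """Read back a quantification CSV written by :func:`write_quant_csv`."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[:8] != list(QUANT_CSV_FIELDS[:8]):
            raise FormatError(f"{path}: unexpected quantification CSV header")
        for row in reader:
            areas = CompartmentAreas(MA=float(row["MA_mm2"]),
                                     SA=float(row["SA_mm2"]),
                                     VA=float(row["VA_mm2"]))
            ratios = RatioSet(
                MA_SA=float(row["MA_SA"]) if row["MA_SA"] else None,
                MA_VA=float(row["MA_VA"]) if row["MA_VA"] else None,
                MA_SAVA=float(row["MA_SAVA"]) if row["MA_SAVA"] else None,
            )
            prov = {key: row[key] for key in QUANT_CSV_FIELDS[8:] if row.get(key)}
            records.append(QuantRecord(subject_id=row["subject_id"],
                                       group=row["group"], areas=areas,
                                       ratios=ratios, provenance=prov))
    return records
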