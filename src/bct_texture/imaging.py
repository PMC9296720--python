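"""Image-stack I/O, polygonal ROIs and mask propagation.

A breast-CT examination is represented as a stack of coronal grey-value
slices with isotropic in-plane pixel spacing.  The region of interest is a
single freehand polygon drawn on one slice; analysis shrinks it inward by a
skin margin (so subcutaneous fat stays out of the statistics) and reuses
the same mask on every slice of the stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from skimage.morphology import disk, erosion

__all__ = [
    "ImageStack",
    "RoiSpec",
    "read_image_stack",
    "write_image_stack",
    "polygon_to_mask",
    "derive_roi_mask",
    "load_roi_json",
    "save_roi_json",
]


@dataclass
class ImageStack:
    """A slice-indexed set of 2-D grey-value rasters.

    Parameters
    ----------
    voxels
        Array of shape ``(n_slices, rows, cols)``.  2-D input is promoted
        to a single-slice stack.
    pixel_spacing_mm
        In-plane pixel edge length in millimetres (isotropic).
    """

    voxels: np.ndarray
    pixel_spacing_mm: float = 0.3

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim == 2:
            v = v[np.newaxis]
        if v.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D voxel array, got ndim={v.ndim}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        self.voxels = v

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]


@dataclass
class RoiSpec:
    """Polygonal region of interest with a skin margin.

    Vertices are ``(x, y) = (column, row)`` pairs in 0-based pixel
    coordinates; pixel membership is decided at pixel centers (a pixel's
    center is at its integer index).  ``slices`` optionally restricts the
    analysis to a subset of slice indices (e.g. to drop slices showing
    chest-wall structures); ``None`` means all slices.
    """

    polygon: Sequence[tuple[float, float]]
    margin_mm: float = 5.0
    slices: Sequence[int] | None = None

    def __post_init__(self) -> None:
        poly = [(float(x), float(y)) for x, y in self.polygon]
        if len(poly) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be non-negative")
        self.polygon = poly


def read_image_stack(path: str | Path, default_spacing_mm: float = 0.3) -> ImageStack:
    """Read a multi-page TIFF or NIfTI file as an :class:`ImageStack`.

    Pixel spacing is taken from the file header where available (NIfTI
    zooms, TIFF resolution tags); otherwise ``default_spacing_mm`` is
    used.  Integer grey values are preserved losslessly.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 2:
            data = data[np.newaxis]
        elif data.ndim == 3:
            # NIfTI stores (x, y, z); slices last -> move to axis 0
            data = np.moveaxis(data, -1, 0)
        else:
            raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")
        zooms = img.header.get_zooms()
        spacing = float(zooms[0]) if len(zooms) >= 1 and zooms[0] > 0 else default_spacing_mm
        return ImageStack(data, pixel_spacing_mm=spacing)

    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        spacing = default_spacing_mm
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None:
            num, den = res.value
            if num > 0 and den > 0:
                per_unit = num / den
                unit_mm = {2: 25.4, 3: 10.0}.get(int(unit.value))
                if unit_mm is not None and per_unit > 0:
                    spacing = unit_mm / per_unit
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF dimensionality {data.ndim}")
    shapes = {tuple(s.shape) for s in data}
    if len(shapes) != 1:  # pragma: no cover - tifffile stacks are regular
        raise ValueError("mixed slice shapes")
    return ImageStack(data, pixel_spacing_mm=spacing)


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (``.tif``) or NIfTI (``.nii[.gz]``)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        s = stack.pixel_spacing_mm
        affine = np.diag([s, s, s, 1.0])
        data = np.moveaxis(stack.voxels, 0, -1)
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        # resolution tag in pixels-per-cm keeps the spacing round-trippable
        per_cm = 10.0 / stack.pixel_spacing_mm
        tifffile.imwrite(
            str(path),
            stack.voxels,
            resolution=(per_cm, per_cm),
            resolutionunit="CENTIMETER",
        )
    return path


def polygon_to_mask(roi: RoiSpec | Sequence[tuple[float, float]], slice_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon on one slice by the even-odd rule.

    A pixel ``(row, col)`` is inside iff its center ``(x=col, y=row)``
    satisfies the even-odd (ray-crossing) rule for the polygon.  Centers
    exactly on a lower edge are included and on an upper edge excluded
    (half-open), so abutting polygons tile without overlap.
    """
    polygon = roi.polygon if isinstance(roi, RoiSpec) else RoiSpec(polygon=roi).polygon
    h, w = slice_shape
    verts = np.asarray(polygon, dtype=float)
    if verts.shape[0] < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    area2 = np.sum(x1 * y2 - x2 * y1)
    if area2 == 0:
        raise ValueError("zero-area polygon")

    yy, xx = np.mgrid[0:h, 0:w]
    px = xx.ravel().astype(float)
    py = yy.ravel().astype(float)
    inside = np.zeros(px.shape, dtype=bool)
    for xa, ya, xb, yb in zip(x1, y1, x2, y2):
        crosses = (ya > py) != (yb > py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = (xb - xa) * (py - ya) / (yb - ya) + xa
        inside ^= crosses & (px < x_int)
    return inside.reshape(h, w)


def derive_roi_mask(stack: ImageStack, roi: RoiSpec) -> np.ndarray:
    """Rasterize, erode by the skin margin, and propagate across slices.

    The polygon is rasterized on one slice, shrunk by morphological
    erosion with a disk of radius ``round(margin_mm / pixel_spacing_mm)``
    pixels, and the eroded mask is replicated unchanged to every slice.
    Slices not listed in ``roi.slices`` (when given) get an all-False mask.

    Raises
    ------
    ValueError
        If erosion removes every pixel — the ROI is too small for the
        requested margin.
    """
    if stack.n_slices < 1:
        raise ValueError("empty stack")
    base = polygon_to_mask(roi, stack.slice_shape)
    radius = int(round(roi.margin_mm / stack.pixel_spacing_mm))
    if radius > 0:
        base = erosion(base, disk(radius))
    if not base.any():
        raise ValueError(
            f"ROI empty after erosion by {radius} px "
            f"(margin {roi.margin_mm} mm at {stack.pixel_spacing_mm} mm/px)"
        )
    mask = np.zeros((stack.n_slices,) + tuple(stack.slice_shape), dtype=bool)
    indices = range(stack.n_slices) if roi.slices is None else roi.slices
    for i in indices:
        mask[i] = base
    return mask


def save_roi_json(roi: RoiSpec, path: str | Path) -> Path:
    path = Path(path)
    payload = {"polygon": [[x, y] for x, y in roi.polygon], "margin_mm": roi.margin_mm}
    if roi.slices is not None:
        payload["slices"] = list(roi.slices)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_roi_json(path: str | Path) -> RoiSpec:
    payload = json.loads(Path(path).read_text())
    return RoiSpec(
        polygon=[tuple(v) for v in payload["polygon"]],
        margin_mm=float(payload.get("margin_mm", 5.0)),
        slices=payload.get("slices"),
    )
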