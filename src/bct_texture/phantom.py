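"""Synthetic breast-CT phantoms with controllable density class.

Coronal breast-CT slices show a roughly disk-shaped breast cross-section
filled with two tissue compartments: fat (low grey values) and glandular
tissue (high grey values), interleaved by thin fatty septae.  The pooled
grey-value histogram of a stack is therefore bimodal, and the balance of
the two peaks tracks the four-level density grade ``a`` (almost entirely
fatty) to ``d`` (extremely dense).

The generator emulates exactly that: per slice, a disk-shaped support is
partitioned into gland and fat by thresholding a smoothed Gaussian random
field at the quantile matching the class's gland volume fraction.  The
smoothing length controls the septal texture scale; Gaussian noise is
added on top.  No X-ray physics, reconstruction or lesions are modelled —
the phantom only reproduces the histogram shape and spatial correlation
structure the texture features respond to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import ImageStack, write_image_stack

__all__ = [
    "DENSITY_CLASSES",
    "DENSITY_ORDINAL",
    "PhantomConfig",
    "PhantomExam",
    "generate_phantom_exam",
    "generate_cohort",
    "support_mask",
    "support_polygon",
    "write_cohort",
]

#: The four density grades, fatty to extremely dense.
DENSITY_CLASSES = ("a", "b", "c", "d")
#: Ordinal coding used for rank correlations (a=1 ... d=4).
DENSITY_ORDINAL = {c: k + 1 for k, c in enumerate(DENSITY_CLASSES)}


def _default_gland_fractions() -> dict[str, float]:
    return {"a": 0.10, "b": 0.35, "c": 0.60, "d": 0.85}


@dataclass
class PhantomConfig:
    """Geometry, tissue intensities and texture scale of the phantom.

    Defaults give a 50-slice stack of 256 x 256 pixels at 0.3 mm spacing;
    gland volume fractions per class increase strictly from ``a`` to
    ``d``.  Intensities are in arbitrary units (normalisation makes the
    features unit-free); ``correlation_length_px`` is the Gaussian
    smoothing sigma that sets the septal texture scale.
    """

    n_slices: int = 50
    slice_shape: tuple[int, int] = (256, 256)
    pixel_spacing_mm: float = 0.3
    breast_radius_frac: float = 0.9
    gland_fraction_by_class: Mapping[str, float] = field(default_factory=_default_gland_fractions)
    fat_mean: float = 30.0
    gland_mean: float = 70.0
    noise_sd: float = 5.0
    correlation_length_px: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or min(self.slice_shape) < 8:
            raise ValueError("non-positive or degenerate phantom dimensions")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not 0 < self.breast_radius_frac <= 1:
            raise ValueError("breast_radius_frac must be in (0, 1]")
        fracs = [self.gland_fraction_by_class[c] for c in DENSITY_CLASSES]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("gland fractions must lie in [0, 1]")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("gland fractions must increase strictly a -> d")
        if self.gland_mean <= self.fat_mean:
            raise ValueError("gland_mean must exceed fat_mean")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.correlation_length_px < 1:
            raise ValueError("correlation_length_px must be >= 1")


@dataclass
class PhantomExam:
    """One synthetic examination: a stack plus its ground truth."""

    stack: ImageStack
    density_label: str
    true_gland_fraction: float
    seed: int
    exam_id: str = ""


def support_mask(config: PhantomConfig) -> np.ndarray:
    """Boolean disk of the breast cross-section (shared by all slices)."""
    h, w = config.slice_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = config.breast_radius_frac * min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def support_polygon(config: PhantomConfig, n_vertices: int = 64) -> list[tuple[float, float]]:
    """Regular polygon tracing the breast-support circle, as an ROI outline."""
    h, w = config.slice_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = config.breast_radius_frac * min(h, w) / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return [(cx + radius * np.cos(t), cy + radius * np.sin(t)) for t in theta]


def generate_phantom_exam(
    config: PhantomConfig,
    density_class: str,
    seed: int,
    gland_fraction_override: float | None = None,
) -> PhantomExam:
    """Generate one examination of the given density class.

    Per slice, a Gaussian random field is smoothed with sigma
    ``correlation_length_px`` and thresholded at the ``1 - gland_fraction``
    quantile of its within-support values, giving a connected gland
    compartment of (almost exactly) the requested area fraction.  Gland
    pixels take ``gland_mean``, fat pixels ``fat_mean``; independent
    Gaussian noise of sd ``noise_sd`` is added; pixels outside the support
    are 0.  Bit-identical for identical ``(config, density_class, seed)``.
    """
    if density_class not in DENSITY_CLASSES:
        raise ValueError(f"unknown density class {density_class!r}")
    gf = (
        float(gland_fraction_override)
        if gland_fraction_override is not None
        else float(config.gland_fraction_by_class[density_class])
    )
    if not 0.0 <= gf <= 1.0:
        raise ValueError("gland fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    support = support_mask(config)
    n_support = int(support.sum())
    h, w = config.slice_shape
    voxels = np.zeros((config.n_slices, h, w), dtype=np.float32)
    gland_pixels = 0
    for sl in range(config.n_slices):
        field_ = gaussian_filter(rng.standard_normal((h, w)), sigma=config.correlation_length_px)
        if gf <= 0.0:
            gland = np.zeros((h, w), dtype=bool)
        elif gf >= 1.0:
            gland = support.copy()
        else:
            thresh = np.quantile(field_[support], 1.0 - gf)
            gland = support & (field_ >= thresh)
        gland_pixels += int(gland.sum())
        img = np.where(gland, config.gland_mean, config.fat_mean)
        img = img + rng.normal(0.0, config.noise_sd, size=(h, w))
        img[~support] = 0.0
        voxels[sl] = img
    realized = gland_pixels / (n_support * config.n_slices)
    stack = ImageStack(voxels, pixel_spacing_mm=config.pixel_spacing_mm)
    return PhantomExam(
        stack=stack,
        density_label=density_class,
        true_gland_fraction=realized,
        seed=seed,
    )


def generate_cohort(config: PhantomConfig, n_per_class: int, seed: int) -> list[PhantomExam]:
    """Balanced cohort of ``4 * n_per_class`` examinations.

    Per-exam seeds are drawn reproducibly from the master seed, so the
    cohort is bit-identical across calls with the same arguments.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    exams: list[PhantomExam] = []
    for cls in DENSITY_CLASSES:
        for k in range(n_per_class):
            exam_seed = int(rng.integers(0, 2**31 - 1))
            exam = generate_phantom_exam(config, cls, exam_seed)
            exam.exam_id = f"{cls}{k:03d}"
            exams.append(exam)
    return exams


def write_cohort(exams: Sequence[PhantomExam], out_dir: str | Path, fmt: str = "tif") -> Path:
    """Write stacks plus a manifest CSV (exam_id, class, seed, fraction, path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for exam in exams:
        fname = f"{exam.exam_id}.{fmt.lstrip('.')}"
        write_image_stack(exam.stack, out_dir / fname)
        rows.append(
            {
                "exam_id": exam.exam_id,
                "density": exam.density_label,
                "seed": exam.seed,
                "true_gland_fraction": exam.true_gland_fraction,
                "path": fname,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
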