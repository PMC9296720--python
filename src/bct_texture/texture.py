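"""Grey-level normalisation and the 19 texture features.

One examination yields one feature vector: grey values inside the ROI are
normalised and quantised to ``N_g`` levels, then the histogram, the
grey-level co-occurrence matrix (GLCM) and the grey-level run-length
matrix (GLRLM) are accumulated over *all* analysed slices before any
feature is computed, so the per-examination value pools the full stack.

Features
--------
First order (histogram): variance, skewness, kurtosis (excess), entropy.
GLCM: contrast, correlation, energy, homogeneity.
GLRLM: SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .imaging import ImageStack, RoiSpec, derive_roi_mask

__all__ = [
    "FEATURE_NAMES",
    "FIRST_ORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "TextureParams",
    "QuantizedRoi",
    "Glcm",
    "Glrlm",
    "normalize_and_quantize",
    "first_order_features",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "extract_features",
    "extract_features_from_mask",
]

FIRST_ORDER_NAMES = ("variance", "skewness", "kurtosis", "entropy")
GLCM_NAMES = ("contrast", "correlation", "energy", "homogeneity")
GLRLM_NAMES = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
)
#: Canonical order of the 19 per-examination texture features.
FEATURE_NAMES = FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES

# In-plane offsets (drow, dcol) for 0, 45, 90 and 135 degrees.
DEFAULT_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class TextureParams:
    """Knobs of the feature extraction.

    ``n_g`` is the number of grey levels after quantisation; co-occurrence
    uses ``glcm_distance`` pixels along each of ``directions``.  Matrix
    counts are accumulated over slices and directions before normalisation
    (set ``per_direction_average`` to average per-direction feature values
    instead).
    """

    n_g: int = 64
    glcm_distance: int = 1
    directions: Sequence[tuple[int, int]] = DEFAULT_DIRECTIONS
    per_direction_average: bool = False

    def __post_init__(self) -> None:
        if self.n_g < 2:
            raise ValueError("n_g must be at least 2")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        if not self.directions:
            raise ValueError("need at least one direction")


@dataclass
class QuantizedRoi:
    """Integer grey levels in ``1..n_g`` inside the mask, undefined outside."""

    levels: np.ndarray
    n_g: int
    mask: np.ndarray

    @property
    def n_masked_pixels(self) -> int:
        return int(self.mask.sum())

    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


@dataclass
class Glcm:
    """Symmetric co-occurrence probabilities accumulated over slices/directions."""

    p: np.ndarray  # (n_g, n_g), sums to 1
    counts: np.ndarray  # raw symmetric pair counts
    distance: int
    directions: tuple[tuple[int, int], ...]


@dataclass
class Glrlm:
    """Run counts ``p[i, j]`` for level ``i+1`` and run length ``j+1``."""

    p: np.ndarray  # (n_g, max_run_length) counts
    n_r: int  # total number of runs
    n_p: int  # masked pixels summed over slices, times number of directions
    directions: tuple[tuple[int, int], ...]


def normalize_and_quantize(stack: ImageStack, mask: np.ndarray, n_g: int = 64) -> QuantizedRoi:
    """Grey-level normalisation: clip to mean +- 3 sd, bin uniformly to 1..n_g.

    Mean and sd are pooled over the masked pixels of all analysed slices,
    which makes every downstream feature invariant to affine rescaling of
    the raw grey values (and so insensitive to scanner calibration drift).
    A constant region (sd = 0) maps every pixel to level 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.voxels.shape:
        raise ValueError("mask shape must match stack shape")
    vals = stack.voxels[mask].astype(float)
    if vals.size == 0:
        raise ValueError("empty mask")
    mu = vals.mean()
    sigma = vals.std()
    levels = np.ones(stack.voxels.shape, dtype=np.int32)
    if sigma > 0:
        lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
        clipped = np.clip(vals, lo, hi)  # only masked pixels are ever read downstream
        binned = np.floor((clipped - lo) / (hi - lo) * n_g).astype(np.int32) + 1
        levels[mask] = np.clip(binned, 1, n_g)
    return QuantizedRoi(levels=levels, n_g=n_g, mask=mask)


def first_order_features(qroi: QuantizedRoi) -> dict[str, float]:
    """Histogram statistics of the pooled masked levels.

    Population (1/N) moments; kurtosis is *excess* kurtosis; entropy is in
    bits over the normalised level histogram.  A constant region returns
    zeros for all four by convention.
    """
    x = qroi.masked_levels().astype(float)
    if x.size == 0:
        raise ValueError("empty ROI")
    mu = x.mean()
    d = x - mu
    var = float(np.mean(d**2))
    if var == 0:
        return {"variance": 0.0, "skewness": 0.0, "kurtosis": 0.0, "entropy": 0.0}
    sd = np.sqrt(var)
    skew = float(np.mean(d**3) / sd**3)
    kurt = float(np.mean(d**4) / sd**4 - 3.0)
    counts = np.bincount(qroi.masked_levels(), minlength=qroi.n_g + 1)[1:]
    h = counts[counts > 0] / x.size
    entropy = float(-np.sum(h * np.log2(h)))
    return {"variance": var, "skewness": skew, "kurtosis": kurt, "entropy": entropy}


def _pair_levels(lvl: np.ndarray, msk: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Level pairs (a, b) at offset (dr, dc) where both pixels are masked."""
    h, w = lvl.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=lvl.dtype), np.empty(0, dtype=lvl.dtype)
    a = lvl[r0:r1, c0:c1]
    b = lvl[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    mm = msk[r0:r1, c0:c1] & msk[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a[mm], b[mm]


def compute_glcm(
    qroi: QuantizedRoi,
    distance: int = 1,
    directions: Sequence[tuple[int, int]] = DEFAULT_DIRECTIONS,
) -> Glcm:
    """Accumulate symmetric co-occurrence counts over slices and directions.

    A pair is counted only when both pixels lie inside the mask;
    symmetrisation counts each ordered pair in both orders.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    n_g = qroi.n_g
    counts = np.zeros(n_g * n_g, dtype=np.int64)
    for sl in range(qroi.levels.shape[0]):
        msk = qroi.mask[sl]
        if not msk.any():
            continue
        lvl = qroi.levels[sl]
        for dr, dc in directions:
            a, b = _pair_levels(lvl, msk, dr * distance, dc * distance)
            if a.size:
                counts += np.bincount((a - 1) * n_g + (b - 1), minlength=n_g * n_g)
    counts = counts.reshape(n_g, n_g)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurring pixel pair found (mask too sparse)")
    return Glcm(
        p=counts / total,
        counts=counts,
        distance=distance,
        directions=tuple(tuple(d) for d in directions),
    )


def glcm_features(g: Glcm) -> dict[str, float]:
    """Contrast, correlation, energy and homogeneity of a normalised GLCM."""
    p = g.p
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("GLCM is not normalised")
    n_g = p.shape[0]
    i = np.arange(1, n_g + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum((ii - jj) ** 2 * p))
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx, my = float(i @ px), float(i @ py)
    sx = np.sqrt(float((i - mx) ** 2 @ px))
    sy = np.sqrt(float((i - my) ** 2 @ py))
    if sx * sy == 0:
        correlation = 1.0  # degenerate single-level region
    else:
        correlation = float(np.sum((ii - mx) * (jj - my) * p) / (sx * sy))
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def _runs_in_rows(lvl: np.ndarray, msk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode each row; unmasked pixels terminate runs.

    Returns (levels, lengths) of all maximal runs, fully vectorised: a
    False separator column is appended so row boundaries never join runs.
    """
    h = lvl.shape[0]
    sep_l = np.zeros((h, 1), dtype=lvl.dtype)
    sep_m = np.zeros((h, 1), dtype=bool)
    flat_l = np.concatenate([lvl, sep_l], axis=1).ravel()
    flat_m = np.concatenate([msk, sep_m], axis=1).ravel()
    prev_m = np.concatenate([[False], flat_m[:-1]])
    prev_l = np.concatenate([[0], flat_l[:-1]])
    starts = flat_m & (~prev_m | (flat_l != prev_l))
    if not starts.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    run_id = np.cumsum(starts) - 1
    lengths = np.bincount(run_id[flat_m])
    levels = flat_l[starts].astype(np.int64)
    return levels, lengths.astype(np.int64)


def _shear_to_rows(a: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rearrange so each (r+1, c+1) diagonal becomes a contiguous row."""
    h, w = a.shape
    rr, cc = np.indices((h, w))
    diag = cc - rr + (h - 1)
    out_l = np.zeros((h + w - 1, h), dtype=a.dtype)
    out_m = np.zeros((h + w - 1, h), dtype=bool)
    out_l[diag, rr] = a
    out_m[diag, rr] = m
    return out_l, out_m


def _slice_runs(lvl: np.ndarray, msk: np.ndarray, direction: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    dr, dc = direction
    if dr < 0:  # scan orientation along a line is irrelevant
        dr, dc = -dr, -dc
    if (dr, dc) == (0, 1) or (dr, dc) == (0, -1):
        return _runs_in_rows(lvl, msk)
    if (dr, dc) == (1, 0):
        return _runs_in_rows(lvl.T, msk.T)
    if (dr, dc) == (1, 1):
        return _runs_in_rows(*_shear_to_rows(lvl, msk))
    if (dr, dc) == (1, -1):
        return _runs_in_rows(*_shear_to_rows(lvl[:, ::-1], msk[:, ::-1]))
    raise ValueError(f"unsupported run direction {direction}")


def compute_glrlm(
    qroi: QuantizedRoi,
    directions: Sequence[tuple[int, int]] = DEFAULT_DIRECTIONS,
) -> Glrlm:
    """Accumulate maximal-run counts over all slices and directions.

    A run is a maximal sequence of masked pixels with equal level along a
    direction; an unmasked pixel (or the mask border) terminates it.
    ``n_p`` is the pooled masked pixel count times the number of
    directions, so ``sum_j j * p[:, j]`` always equals ``n_p``.
    """
    if not directions:
        raise ValueError("need at least one direction")
    mask = qroi.mask
    if not mask.any():
        raise ValueError("empty mask")
    all_levels: list[np.ndarray] = []
    all_lengths: list[np.ndarray] = []
    for sl in range(qroi.levels.shape[0]):
        msk = mask[sl]
        if not msk.any():
            continue
        lvl = qroi.levels[sl]
        for d in directions:
            levels, lengths = _slice_runs(lvl, msk, d)
            all_levels.append(levels)
            all_lengths.append(lengths)
    levels = np.concatenate(all_levels)
    lengths = np.concatenate(all_lengths)
    max_len = int(lengths.max())
    flat = np.bincount((levels - 1) * max_len + (lengths - 1), minlength=qroi.n_g * max_len)
    p = flat.reshape(qroi.n_g, max_len).astype(np.int64)
    n_p = int(mask.sum()) * len(directions)
    return Glrlm(p=p, n_r=int(p.sum()), n_p=n_p, directions=tuple(tuple(d) for d in directions))


def glrlm_features(r: Glrlm) -> dict[str, float]:
    """The eleven run-length statistics (SRE ... LRHGE)."""
    if r.n_r <= 0:
        raise ValueError("GLRLM has no runs")
    p = r.p.astype(float)
    n_g, max_len = p.shape
    i = np.arange(1, n_g + 1, dtype=float)[:, None]  # grey level
    j = np.arange(1, max_len + 1, dtype=float)[None, :]  # run length
    nr = float(r.n_r)
    return {
        "SRE": float(np.sum(p / j**2)) / nr,
        "LRE": float(np.sum(p * j**2)) / nr,
        "GLN": float(np.sum(p.sum(axis=1) ** 2)) / nr,
        "RLN": float(np.sum(p.sum(axis=0) ** 2)) / nr,
        "RP": nr / float(r.n_p),
        "LGRE": float(np.sum(p / i**2)) / nr,
        "HGRE": float(np.sum(p * i**2)) / nr,
        "SRLGE": float(np.sum(p / (i**2 * j**2))) / nr,
        "SRHGE": float(np.sum(p * i**2 / j**2)) / nr,
        "LRLGE": float(np.sum(p * j**2 / i**2)) / nr,
        "LRHGE": float(np.sum(p * i**2 * j**2)) / nr,
    }


def extract_features_from_mask(
    stack: ImageStack, mask: np.ndarray, params: TextureParams | None = None
) -> dict[str, float]:
    """All 19 features from a precomputed boolean mask."""
    params = params or TextureParams()
    qroi = normalize_and_quantize(stack, mask, n_g=params.n_g)
    out: dict[str, float] = {}
    out.update(first_order_features(qroi))
    if params.per_direction_average:
        glcm_acc = {k: 0.0 for k in GLCM_NAMES}
        glrlm_acc = {k: 0.0 for k in GLRLM_NAMES}
        for d in params.directions:
            g = compute_glcm(qroi, distance=params.glcm_distance, directions=[d])
            for k, v in glcm_features(g).items():
                glcm_acc[k] += v
            rr = compute_glrlm(qroi, directions=[d])
            for k, v in glrlm_features(rr).items():
                glrlm_acc[k] += v
        n = len(params.directions)
        out.update({k: v / n for k, v in glcm_acc.items()})
        out.update({k: v / n for k, v in glrlm_acc.items()})
    else:
        g = compute_glcm(qroi, distance=params.glcm_distance, directions=params.directions)
        out.update(glcm_features(g))
        rr = compute_glrlm(qroi, directions=params.directions)
        out.update(glrlm_features(rr))
    return {name: out[name] for name in FEATURE_NAMES}


def extract_features(
    stack: ImageStack, roi: RoiSpec, params: TextureParams | None = None
) -> dict[str, float]:
    """Full per-examination pipeline: mask -> quantise -> 19 pooled features."""
    mask = derive_roi_mask(stack, roi)
    return extract_features_from_mask(stack, mask, params)
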