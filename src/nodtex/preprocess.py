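"""Attenuation normalization, maximum-area slice selection, 8-level quantization.

ROI attenuation is normalized per lesion between mu - 3*sigma and
mu + 3*sigma (mu, sigma = ROI mean and sample standard deviation), mapping
HU onto [0, 1]; texture features are then computed on the axial slice with
the largest masked area, after decimation to 8 gray levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nodtex.roi_io import ROIMask, ROIVoxelList

N_GRAY_LEVELS = 8


@dataclass
class NormalizationParams:
    """ROI mean and standard deviation recorded for auditability."""

    mu: float
    sigma: float  # sample sd (ddof=1); >= 0


@dataclass
class NormalizedROI:
    """An ROI voxel list whose values are normalized attenuation in [0, 1]."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    values: np.ndarray  # unitless, in [0, 1]
    params: NormalizationParams = None
    lesion_id: str = ""

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class QuantizedSlice:
    """One axial slice decimated to gray levels 1..8 inside the in-slice mask."""

    levels: np.ndarray      # 2D int array over the slice bounding box
    mask: np.ndarray        # 2D bool array, same shape
    slice_index: int
    # Continuous normalized values on the same grid; LBP codes are computed
    # from these rather than from the 8-level decimation.
    normalized: np.ndarray = None


def normalize_attenuation(roi: ROIVoxelList) -> NormalizedROI:
    """Map ROI attenuation linearly from [mu-3sigma, mu+3sigma] onto [0, 1].

    Values outside the band are clipped.  A constant ROI (sigma = 0) maps
    to 0.5 everywhere so degenerate phantoms stay processable.
    """
    if len(roi) == 0:
        raise ValueError("cannot normalize an empty ROI")
    v = np.asarray(roi.values, dtype=float)
    mu = float(v.mean())
    sigma = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    if sigma == 0.0:
        norm = np.full_like(v, 0.5)
    else:
        norm = np.clip((v - (mu - 3.0 * sigma)) / (6.0 * sigma), 0.0, 1.0)
    return NormalizedROI(
        x=roi.x, y=roi.y, z=roi.z, values=norm,
        params=NormalizationParams(mu=mu, sigma=sigma),
        lesion_id=roi.lesion_id,
    )


def select_max_area_slice(mask: ROIMask) -> int:
    """Index of the axial slice with the most masked pixels (ties -> smallest)."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    counts = mask.data.sum(axis=(0, 1))
    return int(np.argmax(counts))  # argmax returns the first maximum


def quantize_value(v: np.ndarray) -> np.ndarray:
    """Equal-width 8-bin quantization of [0, 1]: level = 1 + floor(8 v), v=1 -> 8."""
    levels = 1 + np.floor(np.asarray(v, dtype=float) * N_GRAY_LEVELS).astype(int)
    return np.minimum(levels, N_GRAY_LEVELS)


def quantize_gray_levels(roi: NormalizedROI, slice_index: int) -> QuantizedSlice:
    """Decimate the normalized attenuation on one axial slice to 8 gray levels.

    The output arrays cover the slice's in-mask bounding box; levels are
    meaningful only where the 2D mask is True.
    """
    sel = roi.z == slice_index
    if not np.any(sel):
        raise ValueError(f"slice {slice_index} contains no masked voxels")
    xs, ys, vals = roi.x[sel], roi.y[sel], roi.values[sel]
    # Bounding box in (row, col) = (y, x) image convention.
    y0, y1 = int(ys.min()), int(ys.max())
    x0, x1 = int(xs.min()), int(xs.max())
    shape = (y1 - y0 + 1, x1 - x0 + 1)
    mask2d = np.zeros(shape, dtype=bool)
    norm2d = np.zeros(shape, dtype=float)
    mask2d[ys - y0, xs - x0] = True
    norm2d[ys - y0, xs - x0] = vals
    levels = np.zeros(shape, dtype=int)
    levels[mask2d] = quantize_value(norm2d[mask2d])
    return QuantizedSlice(
        levels=levels, mask=mask2d, slice_index=int(slice_index),
        normalized=norm2d,
    )
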