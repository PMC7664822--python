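"""Volume/mask I/O, ROI voxel lists and segmentation agreement.

Coordinate convention
---------------------
Arrays are stored in nibabel's native ``(i, j, k)`` order, interpreted as
``(x, y, z)``: ``x`` = column within an axial slice, ``y`` = row, ``z`` =
axial slice index.  All indices are 0-based.  An axial slice is
``data[:, :, z]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass
class CTVolume:
    """A CT volume with voxel attenuation in Hounsfield units."""

    data: np.ndarray                       # 3D float array, HU
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm per axis
    axis_order: str = "xyz"                # convention tag

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")


@dataclass
class ROIMask:
    """A binary 3D region-of-interest mask paired with a CT volume."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) != 0)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ROIVoxelList:
    """Per-voxel records (x, y, z, HU) for one lesion.

    One record per masked voxel, ordered by z, then y, then x ascending.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    values: np.ndarray
    lesion_id: str = ""

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "z": self.z, "value": self.values}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_shapes(volume_shape: tuple, mask_shape: tuple) -> None:
    if tuple(volume_shape) != tuple(mask_shape):
        raise ValueError(
            f"volume shape {tuple(volume_shape)} does not match "
            f"mask shape {tuple(mask_shape)}"
        )


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI CT volume; voxel size is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data=data, voxel_size=zooms)


def read_mask(path: str | Path) -> ROIMask:
    """Read a NIfTI mask; any nonzero voxel is foreground."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ROIMask(data=data != 0, voxel_size=zooms)


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_volume(volume: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_size))
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


def write_mask(mask: ROIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_size))
    img.header.set_zooms(mask.voxel_size)
    nib.save(img, str(path))


def mask_to_voxel_list(
    volume: CTVolume, mask: ROIMask, lesion_id: str = ""
) -> ROIVoxelList:
    """Convert a masked volume into the ROI-list representation.

    Returns exactly one record per masked voxel with its (x, y, z) indices
    and HU value, in deterministic (z, y, x)-ascending order.
    """
    _check_shapes(volume.data.shape, mask.data.shape)
    if mask.n_voxels == 0:
        raise ValueError("mask is empty: cannot build an ROI list")
    xs, ys, zs = np.nonzero(mask.data)
    order = np.lexsort((xs, ys, zs))  # z major, then y, then x
    xs, ys, zs = xs[order], ys[order], zs[order]
    return ROIVoxelList(
        x=xs, y=ys, z=zs,
        values=volume.data[xs, ys, zs],
        lesion_id=lesion_id,
    )


def dice_coefficient(a: ROIMask, b: ROIMask) -> float:
    """DICE similarity 2|A∩B| / (|A|+|B|) between two segmentations.

    A coefficient above 0.7 is conventionally read as excellent
    inter-observer agreement.
    """
    _check_shapes(a.data.shape, b.data.shape)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("DICE undefined: both masks are empty")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def dice_report(
    pairs: list[tuple[ROIMask, ROIMask]], threshold: float = 0.7
) -> pd.DataFrame:
    """Per-lesion DICE with an excellent-agreement flag, plus mean ± sd.

    The summary row carries lesion id ``__summary__`` with the mean in
    ``dice`` and the sd in ``dice_sd``.
    """
    rows = []
    for i, (a, b) in enumerate(pairs):
        d = dice_coefficient(a, b)
        rows.append({"lesion": str(i), "dice": d, "excellent": d > threshold,
                     "dice_sd": np.nan})
    values = np.array([r["dice"] for r in rows])
    rows.append({
        "lesion": "__summary__",
        "dice": float(values.mean()),
        "excellent": bool((values > threshold).all()),
        "dice_sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    })
    return pd.DataFrame(rows)
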