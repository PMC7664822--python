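"""Synthetic two-class solid-nodule phantoms.

Generates labeled CT-like volumes and masks emulating the statistical
structure the pipeline assumes: ellipsoidal solid lesions in lung-density
background, with class-specific intra-lesion heterogeneity.

* Non-calcified hamartoma (NCH) lesions are multi-component — a random
  blob partition of the mask assigned soft-tissue, fat-like and
  cartilage-like mean attenuations — overlaid with a short-correlation
  Gaussian random field, giving high local contrast.
* Adenocarcinoma (ACA) lesions are single-component soft tissue with a
  long-correlation field, giving a smoother interior.

Heterogeneity is controlled by the per-class correlation length of the
field (NCH strictly shorter than ACA).  No lesion voxel ever reaches the
120 HU calcification threshold; lesions that calcified would have been
diagnosable by eye and are outside the cohort this emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from nodtex.roi_io import CTVolume, ROIMask, write_mask, write_volume

NCH, ACA = "nch", "aca"


@dataclass
class SyntheticCohortConfig:
    """Generator parameters for a two-class nodule cohort.

    Defaults mirror the cohort the pipeline targets: 42 NCH vs 49 ACA,
    largest diameters 14.3 +/- 6.0 mm (NCH) and 22.6 +/- 7.4 mm (ACA)
    truncated to [6, 41] mm, and no voxel at or above the 120 HU
    calcification bound.
    """

    n_class_nch: int = 42
    n_class_aca: int = 49
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    diameter_mean_sd_nch: tuple[float, float] = (14.3, 6.0)
    diameter_mean_sd_aca: tuple[float, float] = (22.6, 7.4)
    diameter_range_mm: tuple[float, float] = (6.0, 41.0)
    background_hu: tuple[float, float] = (-800.0, 30.0)  # lung parenchyma
    aca_base_hu: float = 35.0
    nch_component_hus: tuple[float, ...] = (40.0, -80.0, 80.0)
    nch_blob_scale_mm: float = 6.0
    nch_correlation_length_mm: float = 1.5
    aca_correlation_length_mm: float = 6.0
    texture_sd_hu: float = 80.0
    noise_sd_hu: float = 5.0
    hu_ceiling: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_class_nch < 1 or self.n_class_aca < 1:
            raise ValueError("class counts must be >= 1")
        for mean, sd in (self.diameter_mean_sd_nch, self.diameter_mean_sd_aca):
            if mean <= 0:
                raise ValueError("diameters must be strictly positive")
        if not self.nch_correlation_length_mm < self.aca_correlation_length_mm:
            raise ValueError(
                "heterogeneity ordering violated: NCH correlation length "
                "must be shorter than ACA's"
            )


@dataclass
class SyntheticLesion:
    """One generated lesion: HU volume, binary mask, class label, diameter."""

    volume: CTVolume
    mask: ROIMask
    label: str                 # NCH or ACA
    true_diameter_mm: float
    lesion_id: str = ""
    seed: int = 0


def _draw_diameter(cfg: SyntheticCohortConfig, label: str,
                   rng: np.random.Generator) -> float:
    mean, sd = (cfg.diameter_mean_sd_nch if label == NCH
                else cfg.diameter_mean_sd_aca)
    lo, hi = cfg.diameter_range_mm
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if lo <= d <= hi:
            return float(d)
    raise RuntimeError("diameter rejection sampling failed")  # pragma: no cover


def _correlated_field(shape: tuple[int, ...], corr_mm: float,
                      voxel_mm: tuple[float, ...], sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian white noise smoothed at the correlation length, rescaled to sd."""
    white = rng.standard_normal(shape)
    sigma_vox = [corr_mm / v for v in voxel_mm]
    smooth = gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    s = smooth.std()
    if s > 0:
        smooth = (smooth - smooth.mean()) / s * sd
    return smooth


def generate_nodule(cfg: SyntheticCohortConfig, label: str,
                    seed: int) -> SyntheticLesion:
    """Generate one lesion, deterministic given the seed.

    The mask is an approximately ellipsoidal single connected component of
    the drawn largest diameter; the interior is the class's attenuation
    model; every masked voxel is clipped strictly below ``cfg.hu_ceiling``.
    """
    if label not in (NCH, ACA):
        raise ValueError(f"unknown class label {label!r}")
    rng = np.random.default_rng(seed)
    shape = tuple(cfg.volume_shape)
    voxel = tuple(cfg.voxel_size_mm)

    diameter = _draw_diameter(cfg, label, rng)
    extent = min(s * v for s, v in zip(shape, voxel))
    if diameter >= extent - 2 * max(voxel):
        raise ValueError(
            f"drawn diameter {diameter:.1f} mm does not fit the "
            f"{extent:.0f} mm volume extent"
        )

    # Ellipsoid: largest semi-axis = diameter/2; the others shrunk by a
    # random ratio in [0.7, 1], randomly oriented along the grid axes.
    semi = np.full(3, diameter / 2.0)
    shrink = rng.uniform(0.7, 1.0, size=2)
    axes = rng.permutation(3)
    semi[axes[1]] *= shrink[0]
    semi[axes[2]] *= shrink[1]

    center = (np.array(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist2 = sum(
        ((g - c) * v / a) ** 2
        for g, c, v, a in zip(grids, center, voxel, semi)
    )
    mask = dist2 <= 1.0

    bg_mu, bg_sd = cfg.background_hu
    vol = rng.normal(bg_mu, bg_sd, size=shape)

    if label == NCH:
        # Random blob partition: argmax over smoothed component fields.
        comp_fields = np.stack([
            _correlated_field(shape, cfg.nch_blob_scale_mm, voxel, 1.0, rng)
            for _ in cfg.nch_component_hus
        ])
        comp = np.argmax(comp_fields, axis=0)
        base = np.asarray(cfg.nch_component_hus)[comp]
        texture = _correlated_field(
            shape, cfg.nch_correlation_length_mm, voxel,
            cfg.texture_sd_hu, rng)
    else:
        base = np.full(shape, cfg.aca_base_hu)
        texture = _correlated_field(
            shape, cfg.aca_correlation_length_mm, voxel,
            cfg.texture_sd_hu, rng)

    interior = base + texture + rng.normal(0.0, cfg.noise_sd_hu, size=shape)
    vol[mask] = np.minimum(interior[mask], cfg.hu_ceiling - 1.0)

    return SyntheticLesion(
        volume=CTVolume(data=vol, voxel_size=voxel),
        mask=ROIMask(data=mask, voxel_size=voxel),
        label=label,
        true_diameter_mm=diameter,
        seed=seed,
    )


def _lesion_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-lesion seed derived from the cohort seed."""
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[list[SyntheticLesion], pd.DataFrame]:
    """Generate the full labeled cohort plus its label table.

    NCH lesions come first, then ACA; lesion ids encode class and index.
    The label table has columns id, label, diameter_mm.
    """
    lesions: list[SyntheticLesion] = []
    labels = [NCH] * cfg.n_class_nch + [ACA] * cfg.n_class_aca
    for i, label in enumerate(labels):
        lesion = generate_nodule(cfg, label, _lesion_seed(cfg.seed, i))
        k = i if label == NCH else i - cfg.n_class_nch
        lesion.lesion_id = f"{label}_{k:03d}"
        lesions.append(lesion)
    table = pd.DataFrame({
        "id": [l.lesion_id for l in lesions],
        "label": [l.label for l in lesions],
        "diameter_mm": [l.true_diameter_mm for l in lesions],
    })
    return lesions, table


def write_cohort(lesions: list[SyntheticLesion], table: pd.DataFrame,
                 out_dir: str | Path) -> None:
    """Write per-lesion NIfTI volume/mask pairs plus labels.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for lesion in lesions:
        write_volume(lesion.volume, out / f"{lesion.lesion_id}_vol.nii")
        write_mask(lesion.mask, out / f"{lesion.lesion_id}_mask.nii")
    table.to_csv(out / "labels.csv", index=False)
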