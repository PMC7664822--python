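"""Assembly of the 94-feature panel and the cohort feature matrix.

The feature vector layout is a frozen contract: f1-f8 attenuation
(mass, three sigmoid parameters, four moments), f9-f88 the 20 co-occurrence
features on orientations 0/45/90/135 degrees in that order, f89-f94 LBP.
Class coding in the feature matrix: 0 = adenocarcinoma, 1 = non-calcified
hamartoma.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from nodtex.attenuation import ATTENUATION_FEATURE_NAMES, attenuation_features
from nodtex.glcm import (
    GLCM_FEATURE_NAMES,
    ORIENTATIONS,
    compute_glcm,
    haralick_features,
)
from nodtex.lbp import LBP_FEATURE_NAMES, lbp_codes, lbp_features
from nodtex.preprocess import (
    normalize_attenuation,
    quantize_gray_levels,
    select_max_area_slice,
)
from nodtex.roi_io import CTVolume, ROIMask, mask_to_voxel_list
from nodtex.synthetic import ACA, NCH, SyntheticLesion

logger = logging.getLogger(__name__)

# Frozen index -> name map for f1..f94.
FEATURE_NAMES: tuple[str, ...] = (
    ATTENUATION_FEATURE_NAMES
    + tuple(
        f"glcm{angle:03d}_{name}"
        for angle in ORIENTATIONS
        for name in GLCM_FEATURE_NAMES
    )
    + LBP_FEATURE_NAMES
)
assert len(FEATURE_NAMES) == 94

FEATURE_BLOCKS = {
    "attenuation": slice(0, 8),
    "glcm": slice(8, 88),
    "lbp": slice(88, 94),
    "all": slice(0, 94),
}

LABEL_CODES = {ACA: 0, NCH: 1}


def extract_feature_vector(volume: CTVolume, mask: ROIMask,
                           lesion_id: str = "") -> np.ndarray:
    """Extract the deterministic 94-feature vector for one lesion.

    Attenuation features are 3D (whole ROI); texture features are computed
    on the maximum-area axial slice.
    """
    try:
        roi = mask_to_voxel_list(volume, mask, lesion_id=lesion_id)
        norm = normalize_attenuation(roi)
        f_att = attenuation_features(roi, norm)

        z = select_max_area_slice(mask)
        q = quantize_gray_levels(norm, z)
        f_glcm = np.concatenate([
            np.array([haralick_features(compute_glcm(q, angle))[name]
                      for name in GLCM_FEATURE_NAMES])
            for angle in ORIENTATIONS
        ])
        f_lbp = np.array(list(lbp_features(lbp_codes(q)).values()))
    except Exception as exc:
        raise type(exc)(f"lesion {lesion_id or '<unnamed>'}: {exc}") from exc

    vec = np.concatenate([f_att, f_glcm, f_lbp])
    assert vec.shape == (94,)
    return vec


def build_feature_matrix(
    lesions: list[SyntheticLesion] | list[tuple[CTVolume, ROIMask, str]],
    labels: pd.DataFrame | dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cohort feature matrix: one row per lesion, f1..f94 plus target.

    ``lesions`` is either a list of SyntheticLesion or of
    (volume, mask, lesion_id) tuples, in which case ``labels`` maps
    lesion id -> class name.  Target coding: 0 = ACA, 1 = NCH.
    """
    if labels is not None and isinstance(labels, pd.DataFrame):
        labels = dict(zip(labels["id"], labels["label"]))
    rows, index = [], []
    for item in lesions:
        if isinstance(item, SyntheticLesion):
            vol, mask, lid, lab = item.volume, item.mask, item.lesion_id, item.label
        else:
            vol, mask, lid = item
            lab = labels[lid]
        if lab not in LABEL_CODES:
            raise ValueError(f"unknown label {lab!r} for lesion {lid!r}")
        logger.info("extracting features for %s", lid)
        vec = extract_feature_vector(vol, mask, lesion_id=lid)
        rows.append(np.concatenate([vec, [LABEL_CODES[lab]]]))
        index.append(lid)
    df = pd.DataFrame(rows, index=index,
                      columns=list(FEATURE_NAMES) + ["target"])
    df["target"] = df["target"].astype(int)
    df.index.name = "lesion_id"
    return df


def minmax_normalize_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column linear min-max normalization to [0, 1] (visualization only).

    The target column is left untouched.  Constant columns map to 0.
    Model training must NOT use this (fold-wise scaling avoids leakage).
    """
    out = matrix.copy()
    cols = [c for c in out.columns if c != "target"]
    x = out[cols].to_numpy(dtype=float)
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    out[cols] = (x - lo) / span
    return out
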