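"""Rotation-invariant uniform local binary patterns (riu2) and features f89-f94.

Codes use the square 8-neighborhood at radius 1 on the continuous
normalized attenuation (not the 8-level decimation): a neighbor greater
than or equal to the center sets its bit.  Uniform patterns (at most two
0/1 transitions around the circle) map to their set-bit count 0..8;
non-uniform patterns map to 9, giving a 10-symbol alphabet.  Codes are
defined only where the full 8-neighborhood lies inside the in-slice mask.
"""

from __future__ import annotations

import numpy as np

from nodtex.attenuation import standardized_moments
from nodtex.preprocess import QuantizedSlice

LBP_FEATURE_NAMES = (
    "lbp_mean", "lbp_sd", "lbp_skew", "lbp_kurtosis",
    "lbp_hist_mean", "lbp_entropy",
)

N_LBP_SYMBOLS = 10  # riu2 with 8 neighbors: codes 0..8 plus non-uniform 9

# Neighbors in circular order (clockwise from east) as (row, col) offsets.
_NEIGHBORS = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)


def _riu2_code(bits: np.ndarray) -> np.ndarray:
    """Map 8-bit circular patterns to riu2 codes (vectorized over pixels)."""
    transitions = (bits != np.roll(bits, 1, axis=-1)).sum(axis=-1)
    set_bits = bits.sum(axis=-1)
    return np.where(transitions <= 2, set_bits, 9)


def lbp_codes(q: QuantizedSlice) -> np.ndarray:
    """riu2 codes for every in-mask pixel with a fully masked 8-neighborhood.

    Returns the 1D array of codes (the code multiset; spatial layout is not
    needed by the downstream features, which are rotation invariant).
    """
    img, mask = q.normalized, q.mask
    nrow, ncol = mask.shape
    if nrow < 3 or ncol < 3:
        raise ValueError(
            "lesion slice too small for LBP: no pixel has a full masked "
            "8-neighborhood"
        )
    center = img[1:-1, 1:-1]
    eligible = mask[1:-1, 1:-1].copy()
    bits = np.empty(center.shape + (8,), dtype=bool)
    for b, (dr, dc) in enumerate(_NEIGHBORS):
        nb_img = img[1 + dr:nrow - 1 + dr, 1 + dc:ncol - 1 + dc]
        nb_mask = mask[1 + dr:nrow - 1 + dr, 1 + dc:ncol - 1 + dc]
        eligible &= nb_mask
        bits[..., b] = nb_img >= center
    if not eligible.any():
        raise ValueError(
            "no pixel has a full masked 8-neighborhood; lesion too small for LBP"
        )
    return _riu2_code(bits[eligible])


def lbp_features(codes: np.ndarray) -> dict[str, float]:
    """f89-f94 from the code multiset.

    f89-f92 are mean, sample sd, skew and excess kurtosis of the codes;
    f93 is the mean height of the occupied bins of the normalized code
    histogram; f94 is the base-2 entropy of that histogram.
    """
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("empty LBP code map")
    mean, sd, skew, kurt = standardized_moments(codes.astype(float))
    hist = np.bincount(codes.astype(int), minlength=N_LBP_SYMBOLS) / codes.size
    occupied = hist[hist > 0]
    hist_mean = float(occupied.mean())
    entropy = float(-(occupied * np.log2(occupied)).sum())
    values = (mean, sd, skew, kurt, hist_mean, entropy)
    return dict(zip(LBP_FEATURE_NAMES, values))
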