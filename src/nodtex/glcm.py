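"""Mask-restricted gray-level co-occurrence matrices and the 20-feature block.

Co-occurrence is counted at unit displacement on four orientations of the
maximum-area axial slice, restricted to pixel pairs whose both endpoints
lie inside the in-slice mask, symmetrized and normalized to sum 1.  The 20
Haralick-family features follow the standard published definitions, with
base-2 logarithms and 0*log(0) taken as 0.

Conventions fixed for reproducibility:

* displacement vectors in (row, col): 0 deg -> (0, 1), 45 deg -> (-1, 1),
  90 deg -> (-1, 0), 135 deg -> (-1, -1);
* sum variance uses the sum-average convention;
* normalized inverse difference  = sum p / (1 + |i-j| / N),
  normalized inverse difference moment = sum p / (1 + (i-j)^2 / N^2),
  with N = 8 gray levels;
* correlation and the information measures are defined as 0 when their
  denominators vanish (constant slice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nodtex.preprocess import N_GRAY_LEVELS, QuantizedSlice

ORIENTATIONS = (0, 45, 90, 135)

# (row, col) unit displacement per orientation.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = (
    "autocorrelation", "contrast", "correlation", "cluster_prominence",
    "cluster_shade", "dissimilarity", "energy", "entropy", "homogeneity",
    "maximum_probability", "sum_of_squares", "sum_average", "sum_variance",
    "sum_entropy", "difference_variance", "difference_entropy",
    "imc1", "imc2", "inverse_difference_norm",
    "inverse_difference_moment_norm",
)


@dataclass
class GLCMatrix:
    """An 8x8 symmetric, normalized co-occurrence matrix for one orientation."""

    p: np.ndarray         # (8, 8), entries >= 0, sum 1
    orientation: int      # degrees, one of ORIENTATIONS
    pair_count: int       # ordered pairs contributing (before symmetrization)


def compute_glcm(q: QuantizedSlice, orientation: int) -> GLCMatrix:
    """Count level co-occurrences at the orientation's unit displacement.

    Only pairs with both endpoints inside the in-slice mask contribute.
    Counts are symmetrized (each pair counted in both directions) and
    normalized to a probability matrix.
    """
    if orientation not in _OFFSETS:
        raise ValueError(f"unknown orientation {orientation!r}; "
                         f"expected one of {ORIENTATIONS}")
    dr, dc = _OFFSETS[orientation]
    levels, mask = q.levels, q.mask
    nrow, ncol = mask.shape

    r0s, r0e = max(0, -dr), min(nrow, nrow - dr)
    c0s, c0e = max(0, -dc), min(ncol, ncol - dc)
    src_mask = mask[r0s:r0e, c0s:c0e]
    dst_mask = mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = src_mask & dst_mask
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        raise ValueError(
            f"no valid masked pixel pair at orientation {orientation} deg"
        )
    src = levels[r0s:r0e, c0s:c0e][valid]
    dst = levels[r0s + dr:r0e + dr, c0s + dc:c0e + dc][valid]

    n = N_GRAY_LEVELS
    counts = np.zeros((n, n), dtype=float)
    np.add.at(counts, (src - 1, dst - 1), 1.0)
    counts = counts + counts.T  # symmetrize
    p = counts / counts.sum()
    return GLCMatrix(p=p, orientation=orientation, pair_count=n_pairs)


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0 log 0 = 0."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_features(g: GLCMatrix) -> dict[str, float]:
    """The 20 co-occurrence features, keyed by GLCM_FEATURE_NAMES."""
    p = g.p
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2n and p_{x-y}(k), k = 0..n-1
    p_sum = np.zeros(2 * n - 1)
    p_diff = np.zeros(n)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    ks = np.arange(2, 2 * n + 1)
    kd = np.arange(n)

    autocorrelation = float((ii * jj * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = (autocorrelation - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    dev = ii + jj - mu_x - mu_y
    cluster_prominence = float((dev ** 4 * p).sum())
    cluster_shade = float((dev ** 3 * p).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    energy = float((p ** 2).sum())
    entropy = float(-_xlog2(p).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    maximum_probability = float(p.max())
    sum_of_squares = float(((ii - mu_x) ** 2 * p).sum())
    sum_average = float((ks * p_sum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-_xlog2(p_sum).sum())
    diff_average = float((kd * p_diff).sum())
    difference_variance = float(((kd - diff_average) ** 2 * p_diff).sum())
    difference_entropy = float(-_xlog2(p_diff).sum())

    # Information measures of correlation.
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxy = np.outer(px, py)
    log_pxy = np.zeros_like(pxy)
    nz = pxy > 0
    log_pxy[nz] = np.log2(pxy[nz])
    hxy1 = float(-(p * log_pxy).sum())
    hxy2 = float(-_xlog2(pxy).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    inverse_difference_norm = float(
        (p / (1.0 + np.abs(ii - jj) / n)).sum()
    )
    inverse_difference_moment_norm = float(
        (p / (1.0 + (ii - jj) ** 2 / n ** 2)).sum()
    )

    values = (
        autocorrelation, contrast, correlation, cluster_prominence,
        cluster_shade, dissimilarity, energy, entropy, homogeneity,
        maximum_probability, sum_of_squares, sum_average, sum_variance,
        sum_entropy, difference_variance, difference_entropy,
        imc1, imc2, inverse_difference_norm, inverse_difference_moment_norm,
    )
    return dict(zip(GLCM_FEATURE_NAMES, values))


def pool_orientations(blocks: list[dict[str, float]]) -> dict[str, float]:
    """Per-feature arithmetic mean over the four orientation blocks."""
    if len(blocks) != len(ORIENTATIONS):
        raise ValueError(
            f"expected {len(ORIENTATIONS)} orientation blocks, got {len(blocks)}"
        )
    return {
        name: float(np.mean([b[name] for b in blocks]))
        for name in GLCM_FEATURE_NAMES
    }
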