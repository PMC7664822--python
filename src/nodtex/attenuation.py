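"""The eight 3D attenuation features f1-f8.

f1 (mass) is the mean raw HU over the ROI; f2-f4 are the parameters of a
logistic curve fitted to the empirical cumulative fraction of normalized
attenuation; f5-f8 are mean, standard deviation, skewness and excess
kurtosis of the normalized attenuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from nodtex.preprocess import NormalizedROI
from nodtex.roi_io import ROIVoxelList

ATTENUATION_FEATURE_NAMES = (
    "mass", "sigmoid_amplitude", "sigmoid_location", "sigmoid_scale",
    "attenuation_mean", "attenuation_sd", "attenuation_skew",
    "attenuation_kurtosis",
)


@dataclass
class SigmoidParams:
    """Parameters of f(x) = f2 / (1 + exp(-(x - f3)/f4)).

    ``f2`` is the amplitude, ``f3`` the location (midpoint) and ``f4`` the
    scale, all in normalized-attenuation units.  ``converged`` flags whether
    the least-squares fit reached its residual tolerance.
    """

    f2: float
    f3: float
    f4: float
    converged: bool = True


def mass_feature(roi: ROIVoxelList) -> float:
    """f1: sum of raw ROI voxel intensities divided by the voxel count."""
    if len(roi) == 0:
        raise ValueError("empty ROI")
    return float(np.asarray(roi.values, dtype=float).mean())


def _logistic(x: np.ndarray, f2: float, f3: float, f4: float) -> np.ndarray:
    return f2 / (1.0 + np.exp(-(x - f3) / f4))


def empirical_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and their Hazen plotting positions (i - 0.5)/n."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    frac = (np.arange(1, n + 1) - 0.5) / n
    return x, frac


def fit_sigmoid(roi: NormalizedROI) -> SigmoidParams:
    """Fit the logistic curve to the empirical cumulative fraction.

    x = sorted normalized attenuation, target = cumulative fraction of
    voxels at or below x (Hazen plotting positions).  Initialization
    f2=1, f3=median, f4=sd/2; Levenberg-Marquardt-style least squares to
    residual tolerance 1e-8 or at most 500 iterations; a non-converged fit
    returns the best iterate with ``converged=False`` and a warning.
    """
    v = np.asarray(roi.values, dtype=float)
    if len(np.unique(v)) < 4:
        raise ValueError(
            "sigmoid fit requires at least 4 distinct normalized values "
            f"(got {len(np.unique(v))}); ROI is degenerate"
        )
    x, target = empirical_cdf(v)
    sd = float(v.std(ddof=1))
    p0 = np.array([1.0, float(np.median(v)), max(sd / 2.0, 1e-3)])

    def residuals(p):
        return _logistic(x, *p) - target

    # The target is a cumulative fraction, so the amplitude is O(1); bounding
    # the parameters keeps fits on strongly non-logistic (multi-modal) ROIs
    # from drifting to runaway amplitudes.
    res = least_squares(
        residuals, p0,
        bounds=([0.0, -10.0, 1e-9], [10.0, 10.0, 10.0]),
        ftol=1e-8, xtol=1e-8, gtol=1e-8, max_nfev=500,
    )
    converged = bool(res.status > 0)
    if not converged:
        warnings.warn("sigmoid fit did not converge; returning best iterate")
    f2, f3, f4 = (float(p) for p in res.x)
    return SigmoidParams(f2=f2, f3=f3, f4=f4, converged=converged)


def standardized_moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sample sd, skewness and excess kurtosis.

    Skew and kurtosis are bias-uncorrected standardized central moments
    (m3 / m2^1.5 and m4 / m2^2 - 3); both are defined as 0 when the sd
    is 0.
    """
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    m2 = float(v.var())  # population variance for the standardized moments
    if m2 == 0.0:
        return mean, sd, 0.0, 0.0
    d = v - mean
    skew = float((d ** 3).mean() / m2 ** 1.5)
    kurt = float((d ** 4).mean() / m2 ** 2 - 3.0)
    return mean, sd, skew, kurt


def attenuation_moments(roi: NormalizedROI) -> tuple[float, float, float, float]:
    """f5-f8: mean, sd, skew, excess kurtosis of normalized attenuation."""
    if len(roi) == 0:
        raise ValueError("empty ROI")
    return standardized_moments(roi.values)


def attenuation_features(roi: ROIVoxelList, norm: NormalizedROI) -> np.ndarray:
    """The full f1-f8 block: mass, sigmoid parameters, moments."""
    sig = fit_sigmoid(norm)
    f5, f6, f7, f8 = attenuation_moments(norm)
    return np.array(
        [mass_feature(roi), sig.f2, sig.f3, sig.f4, f5, f6, f7, f8]
    )
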