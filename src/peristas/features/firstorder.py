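"""The 18 standard first-order intensity statistics."""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizationConfig, discretize

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    data: np.ndarray,
    mask: np.ndarray,
    voxel_volume_mm3: float = 1.0,
    cfg: DiscretizationConfig | None = None,
) -> dict[str, float]:
    """First-order statistics of the in-mask intensities.

    Entropy and uniformity are computed on the discretized histogram
    (same binning as the texture matrices); variance, skewness and
    kurtosis are population moments, kurtosis is non-excess (a normal
    distribution scores 3).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("first-order features of an empty mask")
    cfg = cfg or DiscretizationConfig()
    x = np.asarray(data, float)[mask]
    n = x.size

    mean = float(x.mean())
    var = float(x.var())  # population
    p10, p25, med, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))
    robust = x[(x >= p10) & (x <= p90)]

    levels, _ = discretize(data, mask, cfg)
    counts = np.bincount(levels[mask])[1:]
    p = counts[counts > 0] / n

    if var > 0:
        m = x - mean
        skew = float(np.mean(m**3) / var**1.5)
        kurt = float(np.mean(m**4) / var**2)
    else:
        skew, kurt = 0.0, 0.0

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": med,
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
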