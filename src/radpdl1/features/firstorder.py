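"""The 18 first-order intensity statistics of a masked ROI.

Moments use the population convention (divide by n).  Skewness and
kurtosis are defined as 0 for a constant ROI; kurtosis is the plain
(non-excess) standardized fourth moment.  Entropy and uniformity are
computed on the fixed-bin-width discretization of the ROI values.
"""

from __future__ import annotations

import numpy as np

from .discretize import DEFAULT_BIN_WIDTH_HU

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def firstorder_features(roi_values: np.ndarray,
                        voxel_volume_mm3: float = 1.0,
                        bin_width: float = DEFAULT_BIN_WIDTH_HU) -> dict[str, float]:
    x = np.asarray(roi_values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    sd = np.sqrt(var)

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    # discrete probability over fixed-width bins for entropy/uniformity
    levels = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(levels).astype(np.float64) / n
    p = p[p > 0]

    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd ** 3)
        kurt = float(((x - mean) ** 4).mean() / sd ** 4)
    else:
        skew, kurt = 0.0, 0.0

    return {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float(voxel_volume_mm3 * (x ** 2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p ** 2).sum()),
    }
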