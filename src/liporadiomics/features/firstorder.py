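"""First-order (histogram) features of the normalized ROI intensities."""

from __future__ import annotations

import numpy as np

_EPS = np.spacing(1.0)

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
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


def first_order(
    roi_values: np.ndarray,
    voxel_volume_mm3: float,
    levels: np.ndarray | None = None,
) -> dict[str, float]:
    """The 18 first-order features of a 1D array of ROI intensities.

    ``Entropy`` and ``Uniformity`` are histogram features and use the
    discretized gray levels (``levels``, same length as ``roi_values``);
    all other statistics act on the continuous values.  Skewness and
    kurtosis of a zero-variance ROI are defined as 0; kurtosis is the
    raw (non-excess) fourth standardized moment.

    Raises
    ------
    ValueError
        If the ROI is empty.
    """
    x = np.asarray(roi_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("ROI is empty")
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    energy = float((x**2).sum())

    if levels is None:
        levels = np.ones(n, dtype=np.int64)
    lv = np.asarray(levels).ravel()
    if lv.size != n:
        raise ValueError("levels must align with roi_values")
    hist = np.bincount(lv)[1:].astype(float)
    p = hist[hist > 0] / n

    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume_mm3) * energy,
        "Entropy": float(-(p * np.log2(p + _EPS)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": 0.0 if m2 == 0 else float(m3 / m2**1.5),
        "Kurtosis": 0.0 if m2 == 0 else float(m4 / m2**2),
        "Variance": m2,
        "Uniformity": float((p**2).sum()),
    }
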