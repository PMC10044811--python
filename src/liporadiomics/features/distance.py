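"""Tumor-to-bone distance: a depth surrogate for lipomatous tumors.

The feature is the minimum Euclidean distance, in millimetres, between any
tumor voxel centre and any bone voxel centre — i.e. from the closest aspect
of the tumor to the bone.  Overlapping or touching masks give 0.  It is
computed with a Euclidean distance transform of the bone mask (anisotropic
spacing honoured) sampled at tumor voxels, which is exact for the
voxel-centre convention.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def tumor_to_bone_distance(
    tumor_mask: np.ndarray, bone_mask: np.ndarray, spacing_mm
) -> float:
    """Minimum tumor-to-bone voxel-centre distance in mm.

    Raises
    ------
    ValueError
        If either mask is empty or their shapes differ.  Callers that treat
        an absent bone mask as "feature missing" should catch this and
        record a missing value rather than 0.
    """
    tumor = np.asarray(tumor_mask, dtype=bool)
    bone = np.asarray(bone_mask, dtype=bool)
    if tumor.shape != bone.shape:
        raise ValueError(f"mask shapes differ: {tumor.shape} vs {bone.shape}")
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    if not bone.any():
        raise ValueError("bone mask is empty")
    if (tumor & bone).any():
        return 0.0
    # distance from every voxel to the nearest bone voxel centre
    dist = ndimage.distance_transform_edt(~bone, sampling=np.asarray(spacing_mm, float))
    return float(dist[tumor].min())
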