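"""Full feature extraction: 107 radiomic features + tumor-to-bone distance.

Feature names follow the ``<family>_<FeatureName>`` scheme, e.g.
``shape_Sphericity``, ``glcm_Imc2``, ``firstorder_Skewness``; the distance
feature is ``tumor_to_bone_distance``.  Family sizes partition as
18 (first-order) + 14 (shape) + 24 (GLCM) + 16 (GLRLM) + 16 (GLSZM)
+ 14 (GLDM) + 5 (NGTDM) = 107, plus 1 distance = 108.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from liporadiomics.intensity import ImageVolume, discretize, normalize_niv
from liporadiomics.features.firstorder import FIRSTORDER_NAMES, first_order
from liporadiomics.features.shape import SHAPE_NAMES, shape_3d
from liporadiomics.features import texture

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)
GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

DISTANCE_NAME = "tumor_to_bone_distance"

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"firstorder_{n}" for n in FIRSTORDER_NAMES)
    + tuple(f"shape_{n}" for n in SHAPE_NAMES)
    + tuple(f"glcm_{n}" for n in GLCM_NAMES)
    + tuple(f"glrlm_{n}" for n in GLRLM_NAMES)
    + tuple(f"glszm_{n}" for n in GLSZM_NAMES)
    + tuple(f"gldm_{n}" for n in GLDM_NAMES)
    + tuple(f"ngtdm_{n}" for n in NGTDM_NAMES)
    + (DISTANCE_NAME,)
)
RADIOMIC_NAMES: tuple[str, ...] = FEATURE_NAMES[:-1]

assert len(RADIOMIC_NAMES) == 107 and len(FEATURE_NAMES) == 108


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings recorded alongside every feature table.

    bin_width: gray-level bin width in NIV units (fixed-width, min-shifted).
    normalize: apply fat-referenced NIV normalization before extraction.
    gldm_alpha: gray-level tolerance for GLDM dependence.
    """

    bin_width: float = 25.0
    normalize: bool = True
    gldm_alpha: int = 0

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "normalize": self.normalize,
            "gldm_alpha": self.gldm_alpha,
            "glcm_directions": 13,
            "connectivity": 26,
        }


class FeatureExtractionError(RuntimeError):
    """A family failed; the message names the family and feature group."""


def extract_all(
    case=None,
    *,
    volume: ImageVolume | None = None,
    tumor_mask: np.ndarray | None = None,
    bone_mask: np.ndarray | None = None,
    reference_mask: np.ndarray | None = None,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Extract all 108 named features for one lesion.

    Accepts either a phantom case (``case.volume`` plus ``case.masks``) or
    explicit ``volume`` + masks.  An absent/empty bone mask leaves
    ``tumor_to_bone_distance`` as NaN (missing), never 0.  Deterministic
    for fixed input and config.
    """
    config = config or ExtractionConfig()
    if case is not None:
        volume = case.volume
        tumor_mask = case.masks.tumor
        bone_mask = case.masks.bone
        reference_mask = case.masks.reference
    if volume is None or tumor_mask is None:
        raise ValueError("need a case or an explicit volume and tumor mask")
    tumor = np.asarray(tumor_mask, dtype=bool)

    if config.normalize:
        if reference_mask is None:
            raise ValueError("normalization requested but no reference mask given")
        norm = normalize_niv(volume, reference_mask)
        values = norm.voxels
    else:
        values = volume.voxels

    gmap = discretize(values, tumor, bin_width=config.bin_width)
    out: dict[str, float] = {}

    def _run(family: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raise with feature context
            names = [n for n in FEATURE_NAMES if n.startswith(family + "_")]
            raise FeatureExtractionError(
                f"{family} features failed ({names[0]}..{names[-1]}): {exc}"
            ) from exc

    fo = _run(
        "firstorder",
        first_order,
        values[tumor],
        volume.voxel_volume_mm3,
        gmap.roi_levels,
    )
    sh = _run("shape", shape_3d, tumor, volume.spacing_mm)
    lv, nl = gmap.levels, gmap.n_levels
    gc = _run("glcm", texture.glcm, lv, tumor, nl)
    gr = _run("glrlm", texture.glrlm, lv, tumor, nl)
    gz = _run("glszm", texture.glszm, lv, tumor, nl)
    gd = _run("gldm", texture.gldm, lv, tumor, nl, alpha=config.gldm_alpha)
    ng = _run("ngtdm", texture.ngtdm, lv, tumor, nl)

    for prefix, feats in (
        ("firstorder", fo),
        ("shape", sh),
        ("glcm", gc),
        ("glrlm", gr),
        ("glszm", gz),
        ("gldm", gd),
        ("ngtdm", ng),
    ):
        for k, v in feats.items():
            out[f"{prefix}_{k}"] = float(v)

    if bone_mask is not None and np.asarray(bone_mask).any():
        from liporadiomics.features.distance import tumor_to_bone_distance

        out[DISTANCE_NAME] = tumor_to_bone_distance(
            tumor, bone_mask, volume.spacing_mm
        )
    else:
        out[DISTANCE_NAME] = float("nan")

    return {name: out[name] for name in FEATURE_NAMES}


def extract_cohort(cases, config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Feature table for a list of cases: one row per lesion.

    Returns a DataFrame indexed by ``case_id`` with a ``label`` column
    (benign/malignant) followed by the 108 feature columns.
    """
    rows = []
    for case in cases:
        rec = {"case_id": case.case_id, "label": case.label}
        rec.update(extract_all(case, config=config))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("case_id")
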