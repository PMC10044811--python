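"""Synthetic 3D phantom cohorts for the lipoma vs ALT/WDLS problem.

Real T1-weighted volumes of lipomatous tumors are not publicly available,
so every pipeline stage is exercised on seeded synthetic phantoms that
reproduce the class-conditional structure the analysis relies on:

* benign lesions (intramuscular lipomas) are smaller, more elongated,
  internally homogeneous with a negatively skewed voxel histogram, and lie
  farther from bone;
* malignant lesions (ALTs/WDLSs) are larger, more sphere-like, contain
  septa-like bright sheets that raise texture heterogeneity, have
  near-symmetric histograms, and lie closer to bone.

Geometry: the grid's low end along axis 0 is a flat "bone" slab (the
simplest geometry that makes the tumor-to-bone distance informative); the
tumor is a randomly oriented ellipsoid placed so its closest aspect sits a
class-drawn gap above the slab; a small fat-reference cube sits at the
opposite end for intensity normalization.  Raw intensities are multiplied
by a per-case random scanner scale, so downstream results genuinely depend
on NIV normalization.

Reproducibility: one master seed; case ``i`` uses the independent
substream ``default_rng([seed, i])``, so cohorts are identical regardless
of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from liporadiomics.intensity import ImageVolume


class GeometryError(ValueError):
    """Phantom geometry cannot be realized (tumor does not fit, overlap)."""


#: Feature names whose class separation the generator deliberately plants.
#: Four effects drive them: malignant lesions are larger (size/shape and
#: energy features), more sphere-like (compactness), contain bright septa
#: (intensity spread and texture heterogeneity), and lie closer to bone
#: (distance); benign histograms are negatively skewed.
PLANTED_FEATURES: tuple[str, ...] = (
    # compactness and size
    "shape_Sphericity",
    "shape_SurfaceVolumeRatio",
    "shape_Elongation",
    "shape_Flatness",
    "shape_MajorAxisLength",
    "shape_MinorAxisLength",
    "shape_LeastAxisLength",
    "shape_MeshVolume",
    "shape_VoxelVolume",
    "shape_SurfaceArea",
    "shape_Maximum3DDiameter",
    "shape_Maximum2DDiameterSlice",
    "shape_Maximum2DDiameterColumn",
    "shape_Maximum2DDiameterRow",
    # histogram: skew, size-driven energy, septa-driven spread
    "firstorder_Skewness",
    "firstorder_TotalEnergy",
    "firstorder_Energy",
    "firstorder_Variance",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_Range",
    "firstorder_Maximum",
    "firstorder_90Percentile",
    "firstorder_Entropy",
    "firstorder_Uniformity",
    "firstorder_InterquartileRange",
    # septa-driven texture heterogeneity
    "glcm_Contrast",
    "glcm_ClusterShade",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_Imc2",
    "glrlm_LongRunHighGrayLevelEmphasis",
    "glszm_SmallAreaEmphasis",
    "glszm_LargeAreaHighGrayLevelEmphasis",
    # depth
    "tumor_to_bone_distance",
)


@dataclass(frozen=True)
class ClassParams:
    """Per-class generator parameters.

    radius_range_mm: minor semi-axis of the ellipsoidal tumor.
    elongation_range: major/minor semi-axis ratio (1 = sphere).
    septa_intensity_contrast: raw-intensity boost of septa sheets (0 = none).
    noise_sd: within-tumor intensity standard deviation (raw units).
    histogram_skew_target: target skewness of the tumor base intensity draw.
    bone_gap_range_mm: closest tumor-to-bone-slab distance.
    """

    radius_range_mm: tuple[float, float]
    elongation_range: tuple[float, float]
    septa_intensity_contrast: float
    noise_sd: float
    histogram_skew_target: float
    bone_gap_range_mm: tuple[float, float]


BENIGN_DEFAULTS = ClassParams(
    radius_range_mm=(3.5, 6.0),
    elongation_range=(1.4, 2.2),
    septa_intensity_contrast=0.0,
    noise_sd=30.0,
    histogram_skew_target=-1.0,
    bone_gap_range_mm=(8.0, 25.0),
)
MALIGNANT_DEFAULTS = ClassParams(
    radius_range_mm=(6.0, 10.0),
    elongation_range=(1.0, 1.4),
    septa_intensity_contrast=150.0,
    noise_sd=30.0,
    histogram_skew_target=0.0,
    bone_gap_range_mm=(2.0, 12.0),
)

_BONE_SLAB_VOXELS = 3
_SEPTA_THICKNESS_MM = 1.2
_MUSCLE_MEAN = 200.0
_BONE_MEAN = 120.0
_REF_CUBE_VOXELS = 6


@dataclass(frozen=True)
class PhantomSpec:
    """Cohort recipe: counts, grid geometry, class parameters, master seed."""

    n_benign: int = 38
    n_malignant: int = 30
    grid_shape: tuple[int, int, int] = (64, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    benign_params: ClassParams = field(default_factory=lambda: BENIGN_DEFAULTS)
    malignant_params: ClassParams = field(default_factory=lambda: MALIGNANT_DEFAULTS)
    fat_reference_mean: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0 or self.n_benign + self.n_malignant < 1:
            raise ValueError("cohort needs at least one case and no negative counts")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid too small: {self.grid_shape}")
        if self.fat_reference_mean <= 0:
            raise ValueError("fat_reference_mean must be positive")
        for name, p in (("benign", self.benign_params), ("malignant", self.malignant_params)):
            r_lo, r_hi = p.radius_range_mm
            e_lo, e_hi = p.elongation_range
            g_lo, g_hi = p.bone_gap_range_mm
            if not (0 < r_lo <= r_hi):
                raise ValueError(f"{name}: bad radius range {p.radius_range_mm}")
            if not (1.0 <= e_lo <= e_hi):
                raise ValueError(f"{name}: elongation must be >= 1, got {p.elongation_range}")
            if not (0 < g_lo <= g_hi):
                raise ValueError(f"{name}: bone gap must be positive, got {p.bone_gap_range_mm}")
            extent = r_hi * e_hi
            bone_top = (_BONE_SLAB_VOXELS - 1) * self.spacing_mm[0]
            # tumor must end below the fat-reference cube at the far end
            limit = (self.grid_shape[0] - _REF_CUBE_VOXELS - 2) * self.spacing_mm[0]
            if bone_top + g_hi + 2 * extent + self.spacing_mm[0] > limit:
                raise GeometryError(
                    f"{name}: tumor (extent {extent:.1f} mm) plus gap does not fit along axis 0"
                )
            for ax in (1, 2):
                if 2 * extent + 4 > self.grid_shape[ax] * self.spacing_mm[ax]:
                    raise GeometryError(f"{name}: tumor does not fit along axis {ax}")

    def params_for(self, label: str) -> ClassParams:
        if label == "benign":
            return self.benign_params
        if label == "malignant":
            return self.malignant_params
        raise ValueError(f"unknown label {label!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("benign_params", "malignant_params"):
            p = raw[key]
            for k, v in list(p.items()):
                if isinstance(v, list):
                    p[k] = tuple(v)
            raw[key] = ClassParams(**p)
        for key in ("grid_shape", "spacing_mm"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class MaskSet:
    """Co-registered binary label volumes: tumor ROI, bone, fat reference."""

    tumor: np.ndarray
    bone: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.tumor.shape, self.bone.shape, self.reference.shape}
        if len(shapes) != 1:
            raise GeometryError(f"mask shapes differ: {shapes}")
        if not self.tumor.any():
            raise GeometryError("tumor mask is empty")
        if not self.reference.any():
            raise GeometryError("reference mask is empty")
        if (self.tumor & self.bone).any():
            raise GeometryError("tumor overlaps bone")
        if (self.tumor & self.reference).any():
            raise GeometryError("tumor overlaps reference ROI")


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic lesion: image volume, masks, class label, identifier."""

    volume: ImageVolume
    masks: MaskSet
    label: str
    case_id: str


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _skewed_noise(rng, skew: float, sd: float, size: int) -> np.ndarray:
    """Zero-mean noise with given sd and (gamma-family) skewness.

    Negative skew uses a reflected gamma draw; |skew| of a Gamma(k) is
    2/sqrt(k), so k = (2/|skew|)^2 and the scale sets the sd.
    """
    if skew == 0.0:
        return rng.normal(0.0, sd, size)
    k = (2.0 / abs(skew)) ** 2
    theta = sd / np.sqrt(k)
    g = rng.gamma(k, theta, size) - k * theta
    return g if skew > 0 else -g


def generate_case(
    spec: PhantomSpec, label: str, rng_stream: np.random.Generator, case_id: str = "case_000"
) -> PhantomCase:
    """Generate one phantom case for the given class label.

    Placement retries a few times if the realized tumor-to-bone gap falls
    outside the class range (voxelization can shift it by up to one voxel);
    persistent failure raises :class:`GeometryError`.
    """
    params = spec.params_for(label)
    rng = rng_stream
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    bone_top_mm = (_BONE_SLAB_VOXELS - 1) * spacing[0]
    g_lo, g_hi = params.bone_gap_range_mm

    bone = np.zeros(shape, dtype=bool)
    bone[:_BONE_SLAB_VOXELS] = True

    for _attempt in range(10):
        r = rng.uniform(*params.radius_range_mm)
        e = rng.uniform(*params.elongation_range)
        axes = np.array([r * e, r, r])
        rot = _random_rotation(rng)
        extent = np.sqrt(((axes[None, :] * rot) ** 2).sum(axis=1))

        gap = rng.uniform(g_lo, max(g_lo, g_hi - spacing[0]))
        center = np.empty(3)
        center[0] = bone_top_mm + gap + extent[0]
        for ax in (1, 2):
            lo = extent[ax] + spacing[ax]
            hi = (shape[ax] - 1) * spacing[ax] - extent[ax] - spacing[ax]
            if hi < lo:
                raise GeometryError(f"tumor does not fit along axis {ax}")
            center[ax] = rng.uniform(lo, hi)

        tumor = np.zeros(shape, dtype=bool)
        lo_idx = np.maximum(np.floor((center - extent) / spacing).astype(int) - 1, 0)
        hi_idx = np.minimum(np.ceil((center + extent) / spacing).astype(int) + 2, shape)
        if (hi_idx - lo_idx).min() < 1 or hi_idx[0] > shape[0]:
            continue
        grids = np.meshgrid(
            *(np.arange(lo_idx[a], hi_idx[a]) * spacing[a] - center[a] for a in range(3)),
            indexing="ij",
        )
        pts = np.stack(grids, axis=-1) @ rot  # rotate into principal frame
        inside = ((pts / axes) ** 2).sum(axis=-1) <= 1.0
        tumor[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] = inside

        if not tumor.any() or (tumor & bone).any():
            continue
        realized_gap = (np.argwhere(tumor)[:, 0].min() - (_BONE_SLAB_VOXELS - 1)) * spacing[0]
        if g_lo <= realized_gap <= g_hi:
            break
    else:
        raise GeometryError(
            f"could not place {label} tumor with gap in {params.bone_gap_range_mm}"
        )

    reference = np.zeros(shape, dtype=bool)
    c = _REF_CUBE_VOXELS
    reference[shape[0] - c - 1 : shape[0] - 1, 4 : 4 + c, 4 : 4 + c] = True
    if (reference & tumor).any():
        raise GeometryError("tumor extends into the fat-reference region")

    vox = rng.normal(_MUSCLE_MEAN, 20.0, size=shape)
    vox[bone] = rng.normal(_BONE_MEAN, 15.0, size=int(bone.sum()))
    vox[reference] = spec.fat_reference_mean + rng.normal(0.0, 10.0, size=int(reference.sum()))

    n_tumor = int(tumor.sum())
    base = spec.fat_reference_mean
    vox[tumor] = base + _skewed_noise(
        rng, params.histogram_skew_target, params.noise_sd, n_tumor
    )

    if params.septa_intensity_contrast > 0:
        n_septa = int(rng.integers(1, 3))
        t_idx = np.argwhere(tumor) * spacing - center
        boost = np.zeros(n_tumor)
        for _ in range(n_septa):
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            offset = rng.uniform(-0.3 * r, 0.3 * r)
            on_plane = np.abs(t_idx @ normal - offset) < _SEPTA_THICKNESS_MM / 2
            boost[on_plane] = params.septa_intensity_contrast
        vox[tumor] += boost

    scanner_scale = rng.uniform(0.6, 1.8)
    vox *= scanner_scale

    volume = ImageVolume(voxels=vox, spacing_mm=tuple(spacing))
    masks = MaskSet(tumor=tumor, bone=bone, reference=reference)
    return PhantomCase(volume=volume, masks=masks, label=label, case_id=case_id)


def generate_cohort(spec: PhantomSpec) -> list[PhantomCase]:
    """Generate the full cohort: benign cases first, then malignant.

    Case ``i`` uses substream ``default_rng([spec.seed, i])``, so any
    subset of cases is reproducible independently of the others.
    """
    cases = []
    labels = ["benign"] * spec.n_benign + ["malignant"] * spec.n_malignant
    for i, label in enumerate(labels):
        rng = np.random.default_rng([spec.seed, i])
        cases.append(generate_case(spec, label, rng, case_id=f"{label}_{i:03d}"))
    return cases


def cohort_labels(cases: list[PhantomCase]) -> pd.DataFrame:
    return pd.DataFrame(
        {"case_id": [c.case_id for c in cases], "label": [c.label for c in cases]}
    )


def simulate_resegmentation(
    mask: np.ndarray, rng: np.random.Generator, flip_prob: float = 0.25
) -> np.ndarray:
    """Emulate an observer re-drawing a tumor ROI.

    Observers disagree on parts of the boundary, not on the tumor interior:
    each voxel of the one-voxel outer shell is added, and each voxel of the
    inner boundary removed, independently with probability ``flip_prob``.
    (A full 1-voxel erosion/dilation is the limiting case flip_prob = 1 and
    is far harsher than real re-segmentation.)
    """
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    outer = ndimage.binary_dilation(mask) & ~mask
    inner = mask & ~ndimage.binary_erosion(mask)
    out = mask.copy()
    out[outer] = rng.random(int(outer.sum())) < flip_prob
    drop = rng.random(int(inner.sum())) < flip_prob
    idx = np.argwhere(inner)[drop]
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = False
    if not out.any():  # pragma: no cover - tiny masks only
        return mask
    return out


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

_SUFFIXES = {"img": "_img.nii.gz", "tumor": "_tumor.nii.gz", "bone": "_bone.nii.gz",
             "ref": "_ref.nii.gz"}


def write_case(case: PhantomCase, out_dir: str | Path) -> dict[str, Path]:
    """Write image + masks as NIfTI files ``<case_id>_{img,tumor,bone,ref}``."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(case.volume.spacing_mm) + [1.0])
    affine[:3, 3] = case.volume.origin
    paths = {}
    arrays = {
        "img": case.volume.voxels.astype(np.float64),
        "tumor": case.masks.tumor.astype(np.uint8),
        "bone": case.masks.bone.astype(np.uint8),
        "ref": case.masks.reference.astype(np.uint8),
    }
    for key, arr in arrays.items():
        p = out_dir / f"{case.case_id}{_SUFFIXES[key]}"
        nib.save(nib.Nifti1Image(arr, affine), p)
        paths[key] = p
    return paths


def read_case(case_dir: str | Path, case_id: str, label: str) -> PhantomCase:
    """Read a case written by :func:`write_case`.

    Raises
    ------
    GeometryError
        If any mask grid does not match the image grid.
    """
    import nibabel as nib

    case_dir = Path(case_dir)
    imgs = {}
    for key, suffix in _SUFFIXES.items():
        imgs[key] = nib.load(case_dir / f"{case_id}{suffix}")
    shape = imgs["img"].shape
    for key in ("tumor", "bone", "ref"):
        if imgs[key].shape != shape:
            raise GeometryError(
                f"{case_id}: mask '{key}' grid {imgs[key].shape} != image grid {shape}"
            )
    spacing = tuple(float(z) for z in imgs["img"].header.get_zooms()[:3])
    origin = tuple(float(x) for x in imgs["img"].affine[:3, 3])
    volume = ImageVolume(
        voxels=np.asarray(imgs["img"].dataobj, dtype=np.float64),
        spacing_mm=spacing,
        origin=origin,
    )
    masks = MaskSet(
        tumor=np.asarray(imgs["tumor"].dataobj).astype(bool),
        bone=np.asarray(imgs["bone"].dataobj).astype(bool),
        reference=np.asarray(imgs["ref"].dataobj).astype(bool),
    )
    return PhantomCase(volume=volume, masks=masks, label=label, case_id=case_id)


def write_cohort(cases: list[PhantomCase], out_dir: str | Path) -> Path:
    """Write all cases plus a ``manifest.csv`` (case_id, label, file paths)."""
    out_dir = Path(out_dir)
    rows = []
    for case in cases:
        paths = write_case(case, out_dir)
        rows.append(
            {
                "case_id": case.case_id,
                "label": case.label,
                **{f"path_{k}": str(p) for k, p in paths.items()},
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
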