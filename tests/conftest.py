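import numpy as np
import pytest

from liporadiomics.phantom import ClassParams, PhantomSpec


def make_gray_fixture(seed: int, shape=(4, 4, 3), n_levels: int = 3):
    """Random small gray-level map + ROI mask for oracle comparisons."""
    rng = np.random.default_rng(seed)
    lvl = rng.integers(1, n_levels + 1, size=shape).astype(np.int64)
    mask = rng.random(shape) < 0.85
    mask.flat[0] = True  # never empty
    lvl[~mask] = 0
    return lvl, mask, n_levels


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A fast, geometrically valid cohort recipe for pipeline-level tests."""
    return PhantomSpec(
        n_benign=12,
        n_malignant=12,
        grid_shape=(48, 32, 32),
        spacing_mm=(1.0, 1.0, 1.0),
        benign_params=ClassParams(
            radius_range_mm=(2.5, 4.0),
            elongation_range=(1.2, 1.8),
            septa_intensity_contrast=0.0,
            noise_sd=30.0,
            histogram_skew_target=-1.0,
            bone_gap_range_mm=(6.0, 14.0),
        ),
        malignant_params=ClassParams(
            radius_range_mm=(3.5, 5.5),
            elongation_range=(1.0, 1.3),
            septa_intensity_contrast=150.0,
            noise_sd=30.0,
            histogram_skew_target=0.0,
            bone_gap_range_mm=(2.0, 6.0),
        ),
        seed=11,
    )
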