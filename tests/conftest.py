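import numpy as np
import pytest

from osteovasc.phantom import PhantomSpec, generate_phantom
from osteovasc.segmentation import ClassThresholds


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = int((a & b).sum())
    denom = int(a.sum()) + int(b.sum())
    return 2 * inter / denom if denom else 1.0


def midpoint_thresholds(levels) -> ClassThresholds:
    """Oracle thresholds at the midpoints between known intensity levels."""
    bg, marrow, bone, vessel = levels
    return ClassThresholds(
        background_high=(bg + marrow) / 2,
        bone_low=(marrow + bone) / 2, bone_high=(marrow + bone) / 2,
        vessel_low=(bone + vessel) / 2, vessel_high=(bone + vessel) / 2,
    )


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Blur-free, noise-free, leak-free phantom: its own segmentation."""
    spec = PhantomSpec(dims=(96, 96, 96), cortex_outer_radius_um=150.0,
                       noise_sd=0.0, blur_sigma_vox=0.0, n_leaks=0)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default blur and noise at 96 cubed."""
    spec = PhantomSpec(dims=(96, 96, 96), cortex_outer_radius_um=150.0,
                       seed=5, geometry_seed=5)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth
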