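import numpy as np
import pytest

from cervcobb import PhantomSpec, generate_case, select_midsagittal
from cervcobb.volume_io import ROLE_AP, ROLE_LR, ROLE_SI, LabelVolume, SagittalSlice


@pytest.fixture(scope="session")
def straight_case():
    """Noise-free, straight-edged phantom with a 20 degree ground truth."""
    return generate_case(PhantomSpec.from_target(20.0, rng_seed=1), "straight20")


@pytest.fixture(scope="session")
def straight_slice(straight_case):
    return select_midsagittal(straight_case.volume)[1]


def make_rect_slice(spacing=(1.0, 1.0), shape=(60, 60)):
    """Axis-aligned rectangular C2 and C7 bodies on a small grid.

    With unit spacing, C7 spans 10..40 mm anterior and 0..15 mm superior;
    C2 sits 30 mm above it with the same footprint.
    """
    labels = np.zeros(shape, dtype=np.int16)
    labels[10:41, 0:16] = 7   # C7: anterior 10..40, superior 0..15
    labels[10:41, 30:46] = 2  # C2: anterior 10..40, superior 30..45
    return SagittalSlice(labels=labels, spacing_mm=spacing, label_map={"C2": 2, "C7": 7})


def make_tiny_volume(c2_counts, spacing=(1.0, 1.0, 1.0), shape=(None, 12, 12)):
    """Volume whose per-slice C2 voxel counts are prescribed exactly."""
    n = len(c2_counts)
    labels = np.zeros((n, shape[1], shape[2]), dtype=np.int16)
    for i, cnt in enumerate(c2_counts):
        flat = labels[i].reshape(-1)
        flat[:cnt] = 2
    labels[:, -1, -1] = 7  # C7 present somewhere
    return LabelVolume(
        labels=labels,
        spacing_mm=spacing,
        axis_roles={0: ROLE_LR, 1: ROLE_AP, 2: ROLE_SI},
        label_map={"C2": 2, "C7": 7},
    )
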