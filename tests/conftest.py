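import numpy as np
import pytest

from wmius.synthgen import CohortConfig, cohort_in_memory
from wmius.dataio import build_manifest


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject in-memory cohort at 64x64, shared across tests."""
    cfg = CohortConfig(n_subjects=12, wmi_prevalence=0.25,
                       image_size=(64, 64), seed=42)
    records, images, masks = cohort_in_memory(cfg)
    return build_manifest(records), images, masks


def random_masked_levels(rng, n_gray=4, max_side=8):
    """A random quantized ROI on a random small grid with a random mask."""
    from wmius.texture import QuantizedRoi

    h, w = rng.integers(2, max_side + 1, size=2)
    mask = rng.random((h, w)) < 0.75
    if not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    levels = np.zeros((h, w), dtype=np.int32)
    levels[mask] = rng.integers(1, n_gray + 1, size=int(mask.sum()))
    return QuantizedRoi(levels=levels, n_gray=n_gray,
                        n_pixels=int(mask.sum()), mask=mask)
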