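import numpy as np
import pytest

import beadquant as bq


@pytest.fixture(scope="session")
def layout() -> bq.ChipLayout:
    return bq.build_layout()


@pytest.fixture(scope="session")
def imaging() -> bq.ImagingConfig:
    return bq.ImagingConfig()


@pytest.fixture(scope="session")
def noiseless() -> bq.NoiseModel:
    return bq.NoiseModel.noiseless()


@pytest.fixture(scope="session")
def clean_scene(layout, imaging, noiseless):
    """A fully loaded noiseless scene: (bf, fl, truths), zone means 1500/3000."""
    beads, escaped = bq.place_beads(layout, layout.n_sites, p_trap=1.0, seed=11)
    assert escaped == 0
    return bq.render_pair(
        layout, beads, imaging, noiseless,
        {"test": (1500.0, 0.1), "reference": (3000.0, 0.1)}, seed=11,
    )


@pytest.fixture(scope="session")
def default_params(imaging) -> bq.DetectorParams:
    return bq.DetectorParams(expected_radius=imaging.bead_radius_px)


def brute_force_circle_mean(image: np.ndarray, cx: float, cy: float,
                            radius: float) -> tuple[float, int]:
    """Independent per-pixel loop: mean over pixels whose centres lie in the
    circle.  Deliberately scalar so it shares no code with the implementation."""
    total, count = 0.0, 0
    h, w = image.shape
    for row in range(h):
        for col in range(w):
            dx = col + 0.5 - cx
            dy = row + 0.5 - cy
            if dx * dx + dy * dy <= radius * radius:
                total += float(image[row, col])
                count += 1
    return total / count, count
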