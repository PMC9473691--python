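import numpy as np
import pytest

from nmquant import AcquisitionMeta, StimulusWindow
from nmquant.synthetic import make_movie_truth, simulate_functional_movie


@pytest.fixture(scope="session")
def meta():
    """Five-plane 50 Hz acquisition with 268 nm pixels."""
    return AcquisitionMeta()


@pytest.fixture(scope="session")
def stimulus():
    """500 ms step after 1 s trim allowance + 2 s prestim baseline."""
    return StimulusWindow(onset_s=3.0, duration_s=0.5)


@pytest.fixture(scope="session")
def clean_movie(stimulus):
    """Noiseless, drift-free, bleach-free movie: 4 cells, 2 active
    (peak ΔF/F0 = 1.0, rise 0.5 s, half-life 1.0 s)."""
    truth = make_movie_truth(
        n_cells=4, n_active=2, n_volumes=100, shape=(96, 96),
        seed=11, stimulus=stimulus,
    )
    movie, truth = simulate_functional_movie(truth)
    return movie, truth


def brute_force_roi_mean(frame: np.ndarray, center, diameter_px: int) -> float:
    """Enumeration oracle: mean over pixels whose center lies within the
    disk of the given pixel diameter."""
    cy, cx = center
    r = diameter_px / 2.0
    vals = []
    for y in range(frame.shape[0]):
        for x in range(frame.shape[1]):
            if (y - cy) ** 2 + (x - cx) ** 2 <= r * r:
                vals.append(frame[y, x])
    return float(np.mean(vals))
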