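import logging

import numpy as np
import pytest

from copsway.metrics import CopTrajectory

# mixed-model fits on small or degenerate data legitimately warn; keep the
# test log readable
logging.getLogger("copsway").setLevel(logging.ERROR)


def make_circle(r=10.0, f=0.5, fs=100.0, duration=60.0) -> CopTrajectory:
    """Circular COP path: ap = r·sin(2πft), ml = r·cos(2πft).

    Sampled endpoint-exclusive over [0, duration) so the grid covers an
    integer number of cycles exactly and the sampled sinusoids average to
    zero; every feature then has a closed form, making this the package's
    analytic oracle fixture. The analysed interval is (N−1)/fs.
    """
    t = np.arange(round(duration * fs)) / fs
    return CopTrajectory(
        time=t,
        ap=r * np.sin(2 * np.pi * f * t),
        ml=r * np.cos(2 * np.pi * f * t),
    )


def circle_closed_forms(r=10.0, f=0.5, duration=60.0) -> dict[str, float]:
    """Exact feature values for the circle fixture in the fs → ∞ limit.

    ``duration`` should be the trajectory's analysed interval (its
    ``.duration``); only the extensive excursion features depend on it.
    """
    return {
        "MD_COP": r,
        "MD_AP": 2 * r / np.pi,
        "MD_ML": 2 * r / np.pi,
        "RMS_COP": r,
        "RMS_AP": r / np.sqrt(2),
        "RMS_ML": r / np.sqrt(2),
        "ESC_COP": 2 * np.pi * r * f * duration,
        "ESC_AP": 4 * r * f * duration,
        "ESC_ML": 4 * r * f * duration,
        "VEL_COP": 2 * np.pi * r * f,
        "VEL_AP": 4 * r * f,
        "VEL_ML": 4 * r * f,
        "SWAY": np.pi * r ** 2 * f,
        "FREQ_COP": f,
        "FREQ_AP": np.pi * f / 2,
        "FREQ_ML": np.pi * f / 2,
    }


def make_random_trajectory(rng: np.random.Generator,
                           n: int = 400, fs: float = 50.0) -> CopTrajectory:
    """Smooth random walk with offset — a generic sway-like test path."""
    t = np.arange(n) / fs
    ap = np.cumsum(rng.normal(0, 0.8, n)) + rng.normal(0, 5)
    ml = np.cumsum(rng.normal(0, 0.6, n)) + rng.normal(0, 5)
    return CopTrajectory(time=t, ap=ap, ml=ml)


@pytest.fixture
def circle() -> CopTrajectory:
    return make_circle()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240211)
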