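import numpy as np
import pytest

from evocamo import engine, player
from evocamo.genome import random_genome, render_genome


@pytest.fixture(scope="session")
def uniform_grey():
    return np.full((100, 75), 127.0)


@pytest.fixture(scope="session")
def random_images():
    """A handful of rendered random genomes for metric/property tests."""
    return [render_genome(random_genome(s)).astype(np.float64) for s in range(6)]


@pytest.fixture(scope="session")
def small_background():
    return player.generate_background("smooth-noise", (256, 256), seed=127)


@pytest.fixture()
def tiny_scored_generation():
    """4 bugs scored by a constant-ranking player (fitness 4, 3, 2, 1)."""
    gen = engine.init_population(4, seed=0, plays_per_bug=1)
    times = {b.genome.genome_id: t for b, t in zip(gen.population, [4.0, 3.0, 2.0, 1.0])}

    class RankPlayer(player.CaptureTimeModel):
        def __init__(self):
            super().__init__(kind="rank", timeout_s=5.0)

        def __call__(self, bug, rng):
            return times[bug.genome.genome_id]

    engine.score_population(gen, RankPlayer(), plays_per_bug=1, timeout_s=5.0,
                            rng=np.random.default_rng(0))
    return gen


def vertical_grating(period_px: float, amplitude: float = 127.0,
                     shape=(100, 75), phase: float = 0.0) -> np.ndarray:
    """Closed-form grating whose intensity varies along x (vertical stripes)."""
    y, x = np.mgrid[0: shape[0], 0: shape[1]].astype(np.float64) + 0.5
    return 127.0 + amplitude * np.sin(2 * np.pi * x / period_px + phase)


def horizontal_grating(period_px: float, amplitude: float = 127.0,
                       shape=(100, 75), phase: float = 0.0) -> np.ndarray:
    y, x = np.mgrid[0: shape[0], 0: shape[1]].astype(np.float64) + 0.5
    return 127.0 + amplitude * np.sin(2 * np.pi * y / period_px + phase)
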