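"""Synthetic players and backgrounds standing in for human participants.

The original experiment scored targets by how long museum visitors took to
touch them on naturalistic photographic backgrounds.  This module replaces
both ingredients with seeded synthetic equivalents that preserve the
statistical structure the downstream analyses rely on:

* :func:`generate_background` — greyscale textures normalized to mean pixel
  value 127, emulating the greyscale background photograph library;
* the *null* capture-time model — genome-blind lognormal times with a given
  mean and bug-level sd, with per-trial variance inflated by the number of
  plays (trial variance = bug-level variance x plays), so the sd of
  per-bug mean fitness matches the requested bug-level sd;
* the *perceptual* capture-time model — median capture time decreases with a
  target's conspicuousness against the background, with multiplicative
  lognormal noise and faster targets taking longer at equal conspicuousness.
  This is the synthetic structure that lets directional selection against
  conspicuous, high-motion-energy patterns emerge in the simulated game.

All sampled times are strictly positive and capped at the trial timeout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import metrics
from .config import DEFAULT_TIMEOUT_S

BACKGROUND_SIZE = (820, 1237)  # rows, cols: full-screen arena

#: Default perceptual-player parameters.  Base (median) capture time t0 per
#: speed class in seconds, conspicuousness slope k (s per score unit), score
#: saturation s_max, and lognormal noise sd on the log scale.
PERCEPTUAL_DEFAULTS = {
    "t0": {"fast": 1.4, "medium": 1.1, "slow": 0.8},
    "k": 2.0,
    "s_max": 1.0,
    "log_noise_sd": 0.35,
}

DEFAULT_SCORE_WEIGHTS = (1.0, 1.0, 1.0)

__all__ = [
    "generate_background",
    "conspicuousness_score",
    "lognormal_params_from_moments",
    "sample_capture_time",
    "NullPlayer",
    "PerceptualPlayer",
    "simulate_game_session",
]


# ---------------------------------------------------------------------------
# Backgrounds
# ---------------------------------------------------------------------------

def _normalize_mean_127(img: np.ndarray, target_sd: float) -> np.ndarray:
    sd = img.std()
    if sd > 0 and target_sd > 0:
        img = (img - img.mean()) * (target_sd / sd) + 127.0
    else:
        img = np.full_like(img, 127.0)
    # clipping shifts the mean; one corrective pass is enough at these sds
    img = np.clip(img, 0, 255)
    img = np.clip(img + (127.0 - img.mean()), 0, 255)
    return img


def generate_background(
    kind: str = "smooth-noise",
    size: tuple[int, int] = BACKGROUND_SIZE,
    seed: int = 0,
    amplitude_sd: float = 30.0,
) -> np.ndarray:
    """Seeded greyscale background texture with mean pixel value 127 (+/- 0.5).

    Kinds emulate the photographic library's broad texture classes:
    ``smooth-noise`` (band-limited blotches, e.g. leaf litter at a distance),
    ``patchy`` (thresholded blobs, e.g. dappled bark), and
    ``striped-texture`` (oriented quasi-grass).  ``amplitude_sd = 0`` gives a
    uniform 127 field.
    """
    if len(size) != 2 or min(size) < 8:
        raise ValueError(f"size must be (rows, cols) with each >= 8, got {size}")
    rng = np.random.default_rng(seed)
    h, w = int(size[0]), int(size[1])
    white = rng.normal(size=(h, w))
    if kind == "smooth-noise":
        img = gaussian_filter(white, sigma=8.0, mode="wrap")
    elif kind == "patchy":
        base = gaussian_filter(white, sigma=16.0, mode="wrap")
        img = np.tanh(4.0 * base / max(base.std(), 1e-12))
    elif kind == "striped-texture":
        angle = rng.uniform(0, np.pi)
        y, x = np.mgrid[0:h, 0:w].astype(np.float64)
        s = x * np.cos(angle) + y * np.sin(angle)
        period = rng.uniform(12, 40)
        img = np.sin(2 * np.pi * s / period) + 0.6 * gaussian_filter(
            white, sigma=4.0, mode="wrap"
        )
    else:
        raise ValueError(
            f"kind must be one of 'smooth-noise', 'patchy', 'striped-texture'; got {kind!r}"
        )
    out = _normalize_mean_127(img.astype(np.float64), amplitude_sd)
    return out


# ---------------------------------------------------------------------------
# Conspicuousness
# ---------------------------------------------------------------------------

def conspicuousness_score(
    target: np.ndarray,
    background: np.ndarray,
    weights: tuple[float, float, float] = DEFAULT_SCORE_WEIGHTS,
) -> float:
    """How visually salient a target is against a background.

    ``w1 * CV_contrast + w2 * |mean_target - mean_background| / 255 +
    w3 * normalized total Gabor energy``.  Each term is dimensionless and
    O(1); a uniform mid-grey target on a mean-127 background scores exactly
    0.  Higher = easier to spot, which the perceptual player converts into
    shorter capture times.
    """
    w1, w2, w3 = (float(w) for w in weights)
    if not np.all(np.isfinite([w1, w2, w3])):
        raise ValueError("weights must be finite")
    stats = metrics.luminance_stats(target)
    bank = metrics.gabor_bank(np.asarray(target, dtype=np.float64))
    gabor_norm = sum(bank.values()) / (len(bank) * 127.0)
    lum_diff = abs(stats["mean_lum"] - float(np.mean(background))) / 255.0
    return w1 * stats["cv_contrast"] + w2 * lum_diff + w3 * gabor_norm


# ---------------------------------------------------------------------------
# Capture-time models
# ---------------------------------------------------------------------------

def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with the given data-scale moments."""
    if mean <= 0 or sd <= 0:
        raise ValueError(f"mean and sd must be > 0, got mean={mean}, sd={sd}")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


@dataclass
class CaptureTimeModel:
    kind: str
    timeout_s: float = DEFAULT_TIMEOUT_S


@dataclass
class NullPlayer(CaptureTimeModel):
    """Genome-blind control: every trial time is lognormal noise.

    ``mean_s`` and ``sd_s`` are the *bug-level* moments (mean and sd of
    5-play average fitness).  Because a bug's fitness averages
    ``plays_per_bug`` trials, the per-trial variance is the bug-level
    variance multiplied by ``plays_per_bug``.
    """

    kind: str = "null"
    mean_s: float = 1.2
    sd_s: float = 0.4
    plays_per_bug: int = 5

    def __post_init__(self) -> None:
        trial_sd = self.sd_s * np.sqrt(self.plays_per_bug)
        self.log_mu, self.log_sigma = lognormal_params_from_moments(self.mean_s, trial_sd)

    def sample(self, score: float, speed_class: str, rng: np.random.Generator) -> float:
        t = float(np.exp(rng.normal(self.log_mu, self.log_sigma)))
        return min(max(t, 1e-6), self.timeout_s)

    def __call__(self, bug, rng: np.random.Generator) -> float:
        return self.sample(0.0, bug.speed_class, rng)


@dataclass
class PerceptualPlayer(CaptureTimeModel):
    """Synthetic observer whose capture time falls with conspicuousness.

    Median time is ``t0(speed) + k * max(0, s_max - score)``: a perfectly
    cryptic target (score 0) takes ``k * s_max`` seconds longer than a
    maximally conspicuous one, and fast targets have larger ``t0`` (fast
    targets are hardest to catch).  Noise is multiplicative lognormal with
    sd ``log_noise_sd`` on the log scale; times are capped at the timeout.

    Conspicuousness is evaluated against the model's reference background
    and cached per genome id.
    """

    kind: str = "perceptual"
    t0: dict[str, float] = field(default_factory=lambda: dict(PERCEPTUAL_DEFAULTS["t0"]))
    k: float = PERCEPTUAL_DEFAULTS["k"]
    s_max: float = PERCEPTUAL_DEFAULTS["s_max"]
    log_noise_sd: float = PERCEPTUAL_DEFAULTS["log_noise_sd"]
    weights: tuple[float, float, float] = DEFAULT_SCORE_WEIGHTS
    background: np.ndarray | None = None
    texture_library: list | None = None

    def __post_init__(self) -> None:
        if self.background is None:
            self.background = generate_background("smooth-noise", (256, 256), seed=127)
        self._score_cache: dict[str, float] = {}

    def score_genome(self, genome) -> float:
        from .genome import render_genome

        cached = self._score_cache.get(genome.genome_id)
        if cached is None:
            img = render_genome(genome, self.texture_library)
            cached = conspicuousness_score(img, self.background, self.weights)
            self._score_cache[genome.genome_id] = cached
        return cached

    def median_time(self, score: float, speed_class: str) -> float:
        return self.t0[speed_class] + self.k * max(0.0, self.s_max - score)

    def sample(self, score: float, speed_class: str, rng: np.random.Generator) -> float:
        t = self.median_time(score, speed_class)
        if self.log_noise_sd > 0:
            t *= float(np.exp(rng.normal(0.0, self.log_noise_sd)))
        return min(max(t, 1e-6), self.timeout_s)

    def __call__(self, bug, rng: np.random.Generator) -> float:
        return self.sample(self.score_genome(bug.genome), bug.speed_class, rng)


def sample_capture_time(model: CaptureTimeModel, score: float, speed_class: str,
                        rng: np.random.Generator) -> float:
    """Draw one capture time (seconds) from a model; null kinds ignore the score."""
    return model.sample(score, speed_class, rng)


# ---------------------------------------------------------------------------
# Game sessions
# ---------------------------------------------------------------------------

def simulate_game_session(
    model: CaptureTimeModel,
    generation,
    n_trials: int = 20,
    rng: np.random.Generator | None = None,
    n_backgrounds: int = 40,
    session_id: int = 0,
) -> list[dict]:
    """Simulate one player's session: ``n_trials`` targets drawn uniformly
    from the current generation, each on a random background.

    Returns one record per trial with bug id, background id, speed, time, and
    a caught flag (False when the trial timed out).
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng() if rng is None else rng
    pop = generation.population
    records = []
    for trial in range(n_trials):
        bug = pop[int(rng.integers(len(pop)))]
        score = model.score_genome(bug.genome) if hasattr(model, "score_genome") else 0.0
        t = model.sample(score, bug.speed_class, rng)
        records.append(
            {
                "session_id": session_id,
                "trial": trial,
                "genome_id": bug.genome.genome_id,
                "background_id": int(rng.integers(n_backgrounds)),
                "speed": bug.speed_class,
                "time_s": t,
                "caught": t < model.timeout_s,
            }
        )
    return records
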