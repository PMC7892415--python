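"""Motion modelling: movie synthesis, a 2-D Reichardt detector array, and
circular-statistic summaries.

The question asked of this model is what the early visual system "sees"
when a patterned target moves: a short movie is synthesized in which the
target first moves straight up and then turns 15 degrees to the right, and a
two-dimensional array of correlation-type elementary motion detectors (EMDs)
converts each frame pair into a per-pixel motion vector.  Each pixel hosts
two opponent Reichardt pairs, one along x and one along y: the low-pass
delayed signal at a pixel is multiplied with the undelayed signal of its
neighbour at the detector spacing, and the mirror product is subtracted.
The two opponent outputs form a vector whose angle (theta) and length
(radius) are the local motion estimate.

Per-movie summaries (computed after discarding exact-zero vectors, i.e.
locations with no motion signal):

* coherence — the mean resultant length of theta, in [0, 1];
* motion energy — the mean vector length, a proxy for how salient the
  motion is;
* bias — the wrapped absolute difference between the circular mean of theta
  and the veridical trajectory (the circular mean of the two headings).

Angles are degrees counterclockwise from +x (rightward), so "up" is 90.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import render_genome

#: EMD defaults: neighbour spacing in px, first-order low-pass delay time
#: constant in seconds, and movie frame rate in frames/s.
EMD_DEFAULTS = {"spacing_px": 2, "delay_time_constant_s": 0.033, "frame_rate": 60.0}

ZERO_RADIUS = 1e-9  # below this a motion vector counts as "no signal"

__all__ = [
    "Movie",
    "MotionField",
    "MotionSummary",
    "synthesize_movie",
    "emd_field",
    "motion_summary",
    "motion_experiment",
    "circular_mean_deg",
    "wrapped_diff_deg",
]


# ---------------------------------------------------------------------------
# Circular helpers
# ---------------------------------------------------------------------------

def _mean_unit_vector(theta_deg: np.ndarray) -> tuple[float, float]:
    # cos/sin instead of complex exp: identical result, much cheaper
    th = np.deg2rad(np.asarray(theta_deg, dtype=np.float64))
    return float(np.mean(np.cos(th))), float(np.mean(np.sin(th)))


def circular_mean_deg(theta_deg: np.ndarray) -> float:
    """Circular mean direction, degrees in [0, 360)."""
    c, s = _mean_unit_vector(theta_deg)
    return float(np.degrees(np.arctan2(s, c)) % 360.0)


def mean_resultant_length(theta_deg: np.ndarray) -> float:
    c, s = _mean_unit_vector(theta_deg)
    return float(np.hypot(c, s))


def wrapped_diff_deg(a_deg: float, b_deg: float) -> float:
    """Absolute circular difference in [0, 180]."""
    d = (a_deg - b_deg) % 360.0
    return float(min(d, 360.0 - d))


# ---------------------------------------------------------------------------
# Movie synthesis
# ---------------------------------------------------------------------------

@dataclass
class Movie:
    frames: np.ndarray  # (T, H, W) float64
    frame_rate: float
    headings_deg: list[float]  # per displacement step (T-1 entries)

    @property
    def veridical_deg(self) -> float:
        """Circular mean of the distinct segment headings (90 and 75 degrees
        for the default up-then-15-right trajectory gives 82.5)."""
        segments = sorted(set(self.headings_deg))
        return circular_mean_deg(np.asarray(segments))


def _composite_bilinear(frame: np.ndarray, target: np.ndarray, x: float, y: float) -> None:
    """Composite ``target`` onto ``frame`` with its top-left corner at the
    sub-pixel position (x, y), using bilinear splatting of both the target
    and its opaque rectangular mask."""
    h, w = target.shape
    j0, i0 = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - j0, y - i0
    acc_t = np.zeros((h + 1, w + 1))
    acc_m = np.zeros((h + 1, w + 1))
    for di, dj, wt in ((0, 0, (1 - fx) * (1 - fy)), (0, 1, fx * (1 - fy)),
                       (1, 0, (1 - fx) * fy), (1, 1, fx * fy)):
        if wt == 0:
            continue
        acc_t[di:di + h, dj:dj + w] += wt * target
        acc_m[di:di + h, dj:dj + w] += wt
    region = frame[i0:i0 + h + 1, j0:j0 + w + 1]
    region *= 1.0 - acc_m
    region += acc_t


def synthesize_movie(
    target: np.ndarray,
    background: np.ndarray,
    speed_px_s: float = 600.0,
    n_frames: int = 24,
    frame_rate: float = 60.0,
    turn_deg: float = 15.0,
) -> Movie:
    """Movie of the target moving up, then turning ``turn_deg`` to the right.

    The first half of the displacement steps head straight up (90 degrees);
    the remaining steps head ``90 - turn_deg``.  Per-frame displacement is
    ``speed / frame_rate``; sub-pixel positions are rendered by bilinear
    placement.  The start position centres the whole trajectory in the
    frame; a trajectory that cannot fit raises with the first offending
    frame index.
    """
    if n_frames < 2:
        raise ValueError(f"need at least 2 frames, got {n_frames}")
    bg = np.asarray(background, dtype=np.float64)
    tg = np.asarray(target, dtype=np.float64)
    H, W = bg.shape
    h, w = tg.shape
    step = speed_px_s / frame_rate
    n_steps = n_frames - 1
    headings = [90.0] * (n_steps // 2) + [90.0 - turn_deg] * (n_steps - n_steps // 2)
    disp = np.array(
        [[step * np.cos(np.deg2rad(a)), -step * np.sin(np.deg2rad(a))] for a in headings]
    )
    pos = np.vstack([[0.0, 0.0], np.cumsum(disp, axis=0)])  # (T, [x, y])
    # centre the trajectory's bounding box in the frame
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    start = np.array(
        [(W - w - (hi[0] - lo[0])) / 2.0 - lo[0], (H - h - (hi[1] - lo[1])) / 2.0 - lo[1]]
    )
    pos += start
    for t, (x, y) in enumerate(pos):
        if x < 0 or y < 0 or x + w + 1 > W or y + h + 1 > H:
            raise ValueError(
                f"target leaves the {H}x{W} frame at frame {t} "
                f"(position x={x:.1f}, y={y:.1f}); enlarge the background or "
                f"shorten the movie"
            )
    frames = np.empty((n_frames, H, W))
    for t, (x, y) in enumerate(pos):
        frames[t] = bg
        _composite_bilinear(frames[t], tg, x, y)
    return Movie(frames, frame_rate, headings)


# ---------------------------------------------------------------------------
# EMD array
# ---------------------------------------------------------------------------

@dataclass
class MotionField:
    """Per-pixel direction (degrees, [0, 360)) and magnitude per frame pair."""

    theta: np.ndarray  # (T-1, H', W')
    radius: np.ndarray  # (T-1, H', W'), >= 0


def emd_field(
    movie: Movie,
    spacing_px: int = EMD_DEFAULTS["spacing_px"],
    delay_time_constant_s: float = EMD_DEFAULTS["delay_time_constant_s"],
    normalize_contrast: bool = True,
) -> MotionField:
    """Run the opponent Reichardt array over every frame pair.

    Each frame is mean-subtracted (and scaled to [0, 1] contrast units when
    ``normalize_contrast``).  The delayed arm is a first-order recursive
    low-pass with the given time constant, initialized to the first frame so
    a static movie produces an exactly zero field.  For motion toward +x the
    x-opponent output is positive; the y-opponent is converted to the
    upward-positive math convention before the vector is formed.
    """
    frames = np.asarray(movie.frames, dtype=np.float64)
    if frames.shape[0] < 2:
        raise ValueError("EMD needs at least 2 frames")
    if spacing_px < 1:
        raise ValueError(f"spacing_px must be >= 1, got {spacing_px}")
    sig = frames / 255.0 if normalize_contrast else frames.copy()
    sig -= sig.mean(axis=(1, 2), keepdims=True)
    dt = 1.0 / movie.frame_rate
    alpha = dt / (delay_time_constant_s + dt)
    d = spacing_px
    T, H, W = sig.shape
    n_pairs = T - 1
    theta = np.empty((n_pairs, H - d, W - d))
    radius = np.empty_like(theta)
    low = sig[0].copy()  # delayed (low-passed) signal, init -> static gives 0
    for t in range(1, T):
        cur = sig[t]
        # x-axis opponent pair: detectors span columns [j, j+d]
        rx = (low[:, :-d] * cur[:, d:] - cur[:, :-d] * low[:, d:])[: H - d, :]
        # y-axis opponent pair: rows increase downward, so positive output
        # means downward motion; negate for the math convention
        ry = (low[:-d, :] * cur[d:, :] - cur[:-d, :] * low[d:, :])[:, : W - d]
        vx, vy = rx, -ry
        theta[t - 1] = np.degrees(np.arctan2(vy, vx)) % 360.0
        radius[t - 1] = np.hypot(vx, vy)
        low += alpha * (cur - low)
    return MotionField(theta, radius)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class MotionSummary:
    coherence: float
    energy: float
    bias_deg: float
    mean_direction_deg: float
    n_vectors: int
    defined: bool = True


def motion_summary(field: MotionField, veridical_deg: float) -> MotionSummary:
    """Pool all frame pairs and pixels, drop zero vectors, summarize.

    An all-zero field (e.g. a uniform target indistinguishable from the
    background) yields ``defined=False`` rather than NaN arithmetic.
    """
    mask = field.radius > ZERO_RADIUS
    n = int(mask.sum())
    if n == 0:
        return MotionSummary(np.nan, 0.0, np.nan, np.nan, 0, defined=False)
    th = field.theta[mask]
    rad = field.radius[mask]
    c, s = _mean_unit_vector(th)
    mean_dir = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return MotionSummary(
        coherence=float(np.hypot(c, s)),
        energy=float(rad.mean()),
        bias_deg=wrapped_diff_deg(mean_dir, veridical_deg),
        mean_direction_deg=mean_dir,
        n_vectors=n,
        defined=True,
    )


# ---------------------------------------------------------------------------
# Generation-0 motion experiment
# ---------------------------------------------------------------------------

def motion_experiment(
    bugs,
    background: np.ndarray,
    speed_px_s: float = 600.0,
    n_frames: int = 24,
    frame_rate: float = EMD_DEFAULTS["frame_rate"],
    turn_deg: float = 15.0,
    spacing_px: int = EMD_DEFAULTS["spacing_px"],
    delay_time_constant_s: float = EMD_DEFAULTS["delay_time_constant_s"],
    bias_filter_deg: float | None = 6.0,
    texture_library=None,
) -> tuple[pd.DataFrame, dict]:
    """Per-bug motion summaries for a scored generation-0 set, plus the
    fitness regressions.

    For each bug a movie is synthesized and the EMD summaries computed; bugs
    with undefined summaries are excluded (their count is reported).  Two
    ordinary least-squares models are fitted: ``fitness ~ coherence * bias``
    (with interaction) and ``fitness ~ energy``; the energy model is fitted
    both on all defined bugs and, when ``bias_filter_deg`` is set, on the
    subset with bias no greater than that threshold (the 6-degree
    circular-mean-difference filter).
    """
    import statsmodels.formula.api as smf

    rows = []
    n_undefined = 0
    for bug in bugs:
        img = render_genome(bug.genome, texture_library).astype(np.float64)
        movie = synthesize_movie(img, background, speed_px_s, n_frames, frame_rate, turn_deg)
        field = emd_field(movie, spacing_px, delay_time_constant_s)
        summ = motion_summary(field, movie.veridical_deg)
        if not summ.defined:
            n_undefined += 1
            continue
        rows.append(
            {
                "genome_id": bug.genome.genome_id,
                "fitness": bug.fitness,
                "coherence": summ.coherence,
                "energy": summ.energy,
                "bias_deg": summ.bias_deg,
                "mean_direction_deg": summ.mean_direction_deg,
                "n_vectors": summ.n_vectors,
            }
        )
    table = pd.DataFrame(rows)
    results: dict = {"n_undefined": n_undefined, "n_bugs": len(table)}
    if len(table) >= 5:
        inter = smf.ols("fitness ~ coherence * bias_deg", data=table).fit()
        energy_all = smf.ols("fitness ~ energy", data=table).fit()
        results["coherence_bias_interaction"] = {
            "coef": float(inter.params.get("coherence:bias_deg", np.nan)),
            "pvalue": float(inter.pvalues.get("coherence:bias_deg", np.nan)),
        }
        results["fitness_on_energy"] = {
            "slope": float(energy_all.params["energy"]),
            "pvalue": float(energy_all.pvalues["energy"]),
        }
        if bias_filter_deg is not None:
            kept = table[table["bias_deg"] <= bias_filter_deg]
            if len(kept) >= 5:
                energy_f = smf.ols("fitness ~ energy", data=kept).fit()
                results["fitness_on_energy_filtered"] = {
                    "slope": float(energy_f.params["energy"]),
                    "pvalue": float(energy_f.pvalues["energy"]),
                    "n": int(len(kept)),
                }
    return table, results
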