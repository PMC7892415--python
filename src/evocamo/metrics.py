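"""Pattern quantification: luminance statistics, CV contrast, Gabor energy.

A target's pattern is summarized by

* luminance mean / min / max / sd (population sd) and the coefficient of
  variation ``cv = sd / mean`` as a contrast measure;
* a 4 x 4 Gabor bank — orientations {vertical, horizontal, two diagonals} x
  sigmas {2, 4, 8, 16} px — where "energy" is the sd of the Gabor-convolved
  pixel values;
* the same sd statistic restricted to a sigma-wide rectangle flush with each
  target edge, with the kernel oriented orthogonally to that edge.

Kernel: even (cosine-phase) Gabor, wavelength ``2 * sigma``, aspect ratio 1,
support truncated at 3 sigma, mean-subtracted so a uniform field always
scores exactly zero, and L1-normalized so response amplitude is on the
luminance scale.  Convolution uses reflect padding, which keeps the target
border from contributing spurious edge energy.

Orientation convention: "vertical stripes" means intensity varies along x;
the angle names the stripe orientation, measured from that definition.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

ORIENTATIONS_DEG = {"vertical": 0.0, "diag1": 45.0, "horizontal": 90.0, "diag2": 135.0}
SIGMAS_PX = (2.0, 4.0, 8.0, 16.0)
EDGES = ("top", "bottom", "left", "right")

#: The preset of the five most informative pattern measures: luminance sd,
#: vertical/horizontal/diagonal stripe energy, and right-edge energy.  The
#: diagonal channel pools both diagonals; sigma defaults to 4 px.
PRESET5 = ["sd_lum", "gabor_vertical_s4", "gabor_horizontal_s4",
           "gabor_diagonal_s4", "edge_right_s4"]

__all__ = [
    "luminance_stats",
    "gabor_kernel",
    "gabor_energy",
    "gabor_bank",
    "edge_energy",
    "metric_vector",
    "metric_table",
    "PRESET5",
    "ORIENTATIONS_DEG",
    "SIGMAS_PX",
]


def luminance_stats(img: np.ndarray) -> dict[str, float]:
    """Mean, min, max, population sd, and CV contrast of a greyscale image.

    An all-black image (mean 0) gets ``cv = 0`` with ``degenerate = True``.
    """
    a = np.asarray(img, dtype=np.float64)
    if a.size == 0:
        raise ValueError("empty image")
    mean = float(a.mean())
    sd = float(a.std())  # population sd
    degenerate = mean == 0.0
    cv = 0.0 if degenerate else sd / mean
    return {
        "mean_lum": mean,
        "min_lum": float(a.min()),
        "max_lum": float(a.max()),
        "sd_lum": sd,
        "cv_contrast": cv,
        "degenerate": degenerate,
    }


def gabor_kernel(orientation_deg: float, sigma_px: float) -> np.ndarray:
    """Even-symmetric Gabor kernel tuned to stripes at ``orientation_deg``.

    Orientation 0 produces a carrier along x (responds to vertical stripes).
    Wavelength is tied to scale as ``lambda = 2 * sigma``; the isotropic
    Gaussian envelope is truncated at 3 sigma.  The kernel is mean-subtracted
    (zero DC) and L1-normalized to 2 (positive and negative lobes each ~1).
    """
    if sigma_px <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma_px}")
    half = int(np.ceil(3.0 * sigma_px))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    theta = np.deg2rad(orientation_deg)
    # carrier axis: direction along which intensity varies
    xr = x * np.cos(theta) + y * np.sin(theta)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma_px**2))
    wavelength = 2.0 * sigma_px
    k = envelope * np.cos(2.0 * np.pi * xr / wavelength)
    k -= k.mean()
    k /= np.abs(k).sum() / 2.0
    return k


def _convolve_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    a = np.asarray(img, dtype=np.float64)
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    if ph >= a.shape[0] or pw >= a.shape[1]:
        warnings.warn(
            f"Gabor kernel ({kh}x{kw}) larger than image {a.shape}; "
            "reflect padding truncated to image size", stacklevel=3,
        )
        ph, pw = min(ph, a.shape[0] - 1), min(pw, a.shape[1] - 1)
        kernel = kernel[kh // 2 - ph: kh // 2 + ph + 1, kw // 2 - pw: kw // 2 + pw + 1]
    padded = np.pad(a, ((ph, ph), (pw, pw)), mode="reflect")
    return fftconvolve(padded, kernel, mode="valid")


def gabor_response(img: np.ndarray, orientation_deg: float, sigma_px: float) -> np.ndarray:
    return _convolve_reflect(img, gabor_kernel(orientation_deg, sigma_px))


def gabor_energy(img: np.ndarray, orientation_deg: float, sigma_px: float) -> float:
    """Stripe energy: sd of the Gabor-convolved pixel values over the target."""
    return float(gabor_response(img, orientation_deg, sigma_px).std())


def gabor_bank(img: np.ndarray) -> dict[str, float]:
    """All 16 orientation x sigma energies, keyed ``gabor_<orient>_s<sigma>``."""
    out = {}
    for oname, odeg in ORIENTATIONS_DEG.items():
        for sigma in SIGMAS_PX:
            out[f"gabor_{oname}_s{sigma:g}"] = gabor_energy(img, odeg, sigma)
    return out


def edge_energy(img: np.ndarray, edge: str, sigma_px: float) -> float:
    """Stripe energy in the sigma-wide strip flush with one target edge.

    The kernel is oriented orthogonally to the edge: left/right edges use the
    vertical-stripe channel (variation along x), top/bottom the horizontal
    one.  The sd is taken over the strip only.
    """
    if edge not in EDGES:
        raise ValueError(f"edge must be one of {EDGES}, got {edge!r}")
    h, w = np.asarray(img).shape
    lim = h if edge in ("top", "bottom") else w
    if sigma_px > lim / 2:
        raise ValueError(f"sigma {sigma_px} exceeds half the image extent for edge {edge!r}")
    orientation = 90.0 if edge in ("top", "bottom") else 0.0
    resp = gabor_response(img, orientation, sigma_px)
    band = max(1, int(round(sigma_px)))
    strip = {
        "top": resp[:band, :],
        "bottom": resp[-band:, :],
        "left": resp[:, :band],
        "right": resp[:, -band:],
    }[edge]
    return float(strip.std())


def edge_bank(img: np.ndarray) -> dict[str, float]:
    out = {}
    for edge in EDGES:
        for sigma in SIGMAS_PX:
            out[f"edge_{edge}_s{sigma:g}"] = edge_energy(img, edge, sigma)
    return out


def metric_vector(img: np.ndarray) -> dict[str, float]:
    """Full measurement of one target: 5 luminance stats + 16 Gabor + 16 edge
    energies, plus the pooled-diagonal convenience channels."""
    out = dict(luminance_stats(img))
    out.update(gabor_bank(img))
    out.update(edge_bank(img))
    for sigma in SIGMAS_PX:
        out[f"gabor_diagonal_s{sigma:g}"] = 0.5 * (
            out[f"gabor_diag1_s{sigma:g}"] + out[f"gabor_diag2_s{sigma:g}"]
        )
    out["gabor_total"] = sum(
        out[f"gabor_{o}_s{s:g}"] for o in ORIENTATIONS_DEG for s in SIGMAS_PX
    )
    return out


def metric_table(log, texture_library=None, cache: dict | None = None) -> pd.DataFrame:
    """One measured row per (replicate, speed, generation, genome).

    ``log`` is an :class:`~evocamo.engine.EvolutionLog` (or an iterable of
    GenerationRecords).  Because survivors persist across generations,
    metrics are cached by genome id.  A genome that fails to render is kept
    as a flagged row (``render_failed``), never dropped silently.
    """
    from .genome import render_genome  # local import to avoid cycle

    records = getattr(log, "generations", log)
    cache = {} if cache is None else cache
    rows = []
    for gen in records:
        for bug in gen.population:
            base = {
                "replicate_id": gen.replicate_id,
                "speed_class": gen.speed_class,
                "generation": gen.generation_index,
                "genome_id": bug.genome.genome_id,
                "fitness": bug.fitness,
                "plays": bug.plays,
                "render_failed": False,
            }
            mv = cache.get(bug.genome.genome_id)
            if mv is None:
                try:
                    img = render_genome(bug.genome, texture_library)
                    mv = metric_vector(img)
                except Exception:  # noqa: BLE001 - flagged, not dropped
                    mv = {"degenerate": True, "_failed": True}
                cache[bug.genome.genome_id] = mv
            base["render_failed"] = bool(mv.get("_failed", False))
            rows.append({**base, **{k: v for k, v in mv.items() if k != "_failed"}})
    return pd.DataFrame(rows)
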