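"""Lande–Arnold linear selection analysis on the pattern metrics.

Within each (replicate, speed, generation) stratum, traits are z-scored and
fitness is divided by its stratum mean to give relative fitness ``w``
(mean 1).  The vector of linear selection gradients ``beta`` is the
coefficient vector of the multiple least-squares regression of ``w`` on all
standardized traits jointly — gradients, not univariate differentials — so
each entry reads "change in relative fitness per standard deviation of the
trait, holding the other traits fixed".

Metric pre-selection mirrors the study design of reducing a redundant
metric set to its most informative members: greedy forward selection on an
ordinary linear model of log fitness, minimizing AIC.

Strata that cannot support the regression (too few bugs, zero-variance
traits after convergence, rank deficiency) are flagged and skipped — never
silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import PRESET5

STRATUM_KEYS = ["replicate_id", "speed_class", "generation"]

__all__ = [
    "SelectionGradient",
    "standardize_and_relativize",
    "selection_gradients",
    "select_informative_metrics",
    "gradient_trajectory",
    "PRESET5",
]


@dataclass
class SelectionGradient:
    generation_index: int
    speed_class: str
    replicate_id: int
    traits: list[str]
    beta: np.ndarray
    dropped_traits: list[str]
    flags: list[str]


def standardize_and_relativize(
    table: pd.DataFrame, traits: list[str]
) -> tuple[pd.DataFrame, pd.Series, list[str], list[str]]:
    """Z-score traits and compute relative fitness within one stratum.

    Returns ``(z, w, kept_traits, flags)``.  Zero-variance traits are dropped
    with a flag; all-identical fitness yields ``w`` of ones with a flag (the
    resulting beta is a zero vector).
    """
    flags: list[str] = []
    fitness = table["fitness"].astype(float)
    n = len(table)
    if n < len(traits) + 2:
        raise ValueError(
            f"stratum has {n} bugs but needs at least {len(traits) + 2} "
            f"for {len(traits)} traits"
        )
    kept, z_cols = [], {}
    for t in traits:
        col = table[t].astype(float)
        sd = col.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            flags.append(f"dropped zero-variance trait {t!r}")
            continue
        kept.append(t)
        z_cols[t] = (col - col.mean()) / sd
    z = pd.DataFrame(z_cols, index=table.index)
    mean_fit = fitness.mean()
    if mean_fit <= 0 or fitness.std(ddof=0) == 0:
        flags.append("degenerate fitness (constant or non-positive mean)")
        w = pd.Series(np.ones(n), index=table.index)
    else:
        w = fitness / mean_fit
    return z, w, kept, flags


def selection_gradients(z: pd.DataFrame, w: pd.Series) -> np.ndarray:
    """beta = least-squares coefficients of w on all z-traits jointly.

    Collinear traits are detected via the rank of the design matrix; callers
    should drop flagged traits first (see :func:`gradient_trajectory`).
    """
    if z.shape[1] == 0:
        return np.zeros(0)
    X = np.column_stack([np.ones(len(z)), z.to_numpy(float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {X.shape[1]}; drop collinear traits"
        )
    coef, *_ = np.linalg.lstsq(X, w.to_numpy(float), rcond=None)
    return coef[1:]


def _drop_collinear(z: pd.DataFrame, flags: list[str]) -> pd.DataFrame:
    """Greedily drop later columns until the design matrix has full rank.

    Drop order is documented: later columns in trait order go first.
    """
    cols = list(z.columns)
    while cols:
        X = np.column_stack([np.ones(len(z)), z[cols].to_numpy(float)])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        dropped = cols.pop()  # last-listed trait dropped first
        flags.append(f"dropped collinear trait {dropped!r}")
    return z[cols]


def stratum_gradient(table: pd.DataFrame, traits: list[str]) -> SelectionGradient:
    """Full per-stratum computation: standardize, relativize, regress."""
    z, w, kept, flags = standardize_and_relativize(table, traits)
    z = _drop_collinear(z[kept], flags)
    kept = list(z.columns)
    beta = selection_gradients(z, w)
    first = table.iloc[0]
    return SelectionGradient(
        generation_index=int(first["generation"]),
        speed_class=str(first["speed_class"]),
        replicate_id=int(first["replicate_id"]),
        traits=kept,
        beta=beta,
        dropped_traits=[t for t in traits if t not in kept],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Metric pre-selection
# ---------------------------------------------------------------------------

def select_informative_metrics(
    table: pd.DataFrame, k: int = 5, candidates: list[str] | None = None
) -> list[str]:
    """Greedy forward selection of the ``k`` best predictors of log fitness.

    At each step the candidate whose addition minimizes the AIC of the OLS
    fit of ``log(fitness)`` is added; ties break on column order, so the
    procedure is deterministic given the table.
    """
    import statsmodels.api as sm

    if candidates is None:
        candidates = [
            c
            for c in table.columns
            if c.startswith(("gabor_", "edge_")) or c in ("sd_lum", "cv_contrast")
        ]
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate metrics")
    if k == 0:
        return []
    ok = table["fitness"].astype(float) > 0
    y = np.log(table.loc[ok, "fitness"].astype(float).to_numpy())
    Xall = table.loc[ok, candidates].astype(float)
    Xall = (Xall - Xall.mean()) / Xall.std(ddof=0).replace(0, np.nan)
    chosen: list[str] = []
    remaining = [c for c in candidates if Xall[c].notna().all()]
    while len(chosen) < k and remaining:
        best, best_aic = None, np.inf
        for c in remaining:
            X = sm.add_constant(Xall[chosen + [c]].to_numpy())
            aic = sm.OLS(y, X).fit().aic
            if aic < best_aic - 1e-12:
                best, best_aic = c, aic
        chosen.append(best)
        remaining.remove(best)
    return chosen


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def gradient_trajectory(
    table: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """beta per (replicate, speed, generation), plus replicate averages.

    ``table`` is a metric table with fitness (one row per bug).  Strata that
    fail the preconditions are skipped with a flag row rather than imputed.
    Returns ``(per_stratum, averaged)`` tidy frames; ``averaged`` has one row
    per (speed, generation, trait) with beta averaged across replicates.
    """
    traits = PRESET5 if traits is None else traits
    rows = []
    for keys, sub in table.groupby(STRATUM_KEYS, sort=True):
        rep, speed, gen = keys
        sub = sub[sub["fitness"].notna()]
        try:
            grad = stratum_gradient(sub, traits)
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append(
                {
                    "replicate_id": rep, "speed_class": speed, "generation": gen,
                    "trait": None, "beta": np.nan, "flag": str(exc),
                }
            )
            continue
        flag = "; ".join(grad.flags) if grad.flags else ""
        for t, b in zip(grad.traits, grad.beta):
            rows.append(
                {
                    "replicate_id": rep, "speed_class": speed, "generation": gen,
                    "trait": t, "beta": float(b), "flag": flag,
                }
            )
        for t in grad.dropped_traits:
            rows.append(
                {
                    "replicate_id": rep, "speed_class": speed, "generation": gen,
                    "trait": t, "beta": np.nan, "flag": flag or "dropped",
                }
            )
    per_stratum = pd.DataFrame(rows)
    valid = per_stratum[per_stratum["trait"].notna()]
    averaged = (
        valid.groupby(["speed_class", "generation", "trait"], sort=True)["beta"]
        .mean()
        .reset_index()
    )
    return per_stratum, averaged


def generation_trend(series: np.ndarray) -> tuple[float, float]:
    """Directional-trend test for a per-generation population-mean series.

    Returns ``(slope, pvalue)``.  The slope is the OLS regression of the
    series on generation index.  Because overlapping replacement makes
    successive generation means strongly autocorrelated (the series is close
    to a random walk under a genome-blind player), the OLS t-test would be
    anticonservative; significance is therefore assessed with a one-sample
    t-test on the first differences of the series, which tests for a
    systematic per-generation drift and keeps its nominal size for a
    driftless random walk.
    """
    from scipy import stats

    y = np.asarray(series, dtype=float)
    if len(y) < 3:
        raise ValueError(f"need at least 3 generations, got {len(y)}")
    x = np.arange(len(y), dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    diffs = np.diff(y)
    if np.allclose(diffs, diffs[0]):
        pvalue = 1.0 if np.allclose(diffs, 0.0) else 0.0
    else:
        pvalue = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    return slope, pvalue


def mean_metric_series(table: pd.DataFrame, metric: str) -> pd.Series:
    """Population mean of one metric per generation (single-population table)."""
    return table.groupby("generation", sort=True)[metric].mean()


def quadratic_generation_fit(averaged: pd.DataFrame) -> pd.DataFrame:
    """Quadratic-in-generation summary of each averaged beta series."""
    rows = []
    for (speed, trait), sub in averaged.groupby(["speed_class", "trait"]):
        sub = sub.dropna(subset=["beta"])
        if len(sub) < 3:
            continue
        coefs = np.polyfit(sub["generation"].to_numpy(float), sub["beta"].to_numpy(float), 2)
        rows.append(
            {
                "speed_class": speed, "trait": trait,
                "quad": coefs[0], "lin": coefs[1], "intercept": coefs[2],
            }
        )
    return pd.DataFrame(rows)
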