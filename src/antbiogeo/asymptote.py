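"""Asymptotic "active species" estimation from rarefaction trajectories.

Because any bounded area holds finitely many species at one time, a
species-accumulation curve saturates; its asymptote S estimates the number of
*active* species — those that could be collected given unbounded effort within
the sampled spatial and temporal window. Each rarefaction iteration is fitted
separately, fits of S = 0 (a curve-fitting failure mode, since ants were
collected every week) and the top and bottom 10% of estimates are discarded,
and the surviving estimates are summarized as mean +/- SD.

The default saturating family is S(N) = S * (1 - exp(-q*N)); a three-parameter
logistic S / (1 + c * exp(-q*N)) is available via ``family="logistic3"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import EstimationError, ParameterError
from .occurrence import EventTable
from .rarefaction import DEFAULT_ITERATIONS, rarefy

#: |S_hat| below this is treated as the "S = 0" failure mode.
ZERO_TOL = 1e-6
DEFAULT_TRIM = 0.10


@dataclass(frozen=True)
class AsymptoteFit:
    s_hat: float
    q_hat: float
    converged: bool
    rss: float


@dataclass(frozen=True)
class ActiveSpeciesEstimate:
    """Trimmed-mean asymptote estimate for one scope unit (year or a week)."""

    scope: str
    s_mean: float
    s_sd: float
    s_obs: int
    n_events: int
    n_fits_attempted: int
    n_removed_zero: int
    n_removed_tails: int


def _sat_exp(n, s, q):
    return s * (1.0 - np.exp(-q * n))


def _logistic3(n, s, q, c):
    return s / (1.0 + c * np.exp(-q * n))


def fit_asymptote(
    trajectory,
    family: str = "exponential",
) -> AsymptoteFit:
    """Nonlinear least-squares fit of a saturating curve to one trajectory.

    ``trajectory`` is either a sequence of S_obs values at N = 1..len, or a
    pair of (N, S_obs) arrays. Initialization: S0 = 1.1 * max(S_obs),
    q0 = 1 / median(N); S is bounded in [0, 10 * max(S_obs)]. A failed
    optimization returns ``converged=False`` rather than raising.
    """
    if isinstance(trajectory, tuple) and len(trajectory) == 2:
        n, y = np.asarray(trajectory[0], float), np.asarray(trajectory[1], float)
    else:
        y = np.asarray(trajectory, float)
        n = np.arange(1, len(y) + 1, dtype=float)
    if len(np.unique(n)) < 3:
        raise ParameterError("asymptote fit requires at least 3 distinct N values")

    s_max = float(y.max())
    s0 = 1.1 * s_max if s_max > 0 else 1.0
    q0 = 1.0 / float(np.median(n))
    upper_s = max(10.0 * s_max, 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "exponential":
                popt, _ = curve_fit(
                    _sat_exp, n, y, p0=[s0, q0],
                    bounds=([0.0, 1e-9], [upper_s, 100.0]),
                    jac=lambda n_, s, q: np.stack(
                        [1.0 - np.exp(-q * n_), s * n_ * np.exp(-q * n_)], axis=1
                    ),
                    maxfev=2000,
                )
                s_hat, q_hat = float(popt[0]), float(popt[1])
                resid = y - _sat_exp(n, *popt)
            elif family == "logistic3":
                popt, _ = curve_fit(
                    _logistic3, n, y, p0=[s0, q0, 1.0],
                    bounds=([0.0, 1e-9, 1e-9], [upper_s, 100.0, 1e6]),
                    maxfev=5000,
                )
                s_hat, q_hat = float(popt[0]), float(popt[1])
                resid = y - _logistic3(n, *popt)
            else:
                raise ParameterError(f"unknown asymptote family {family!r}")
    except (RuntimeError, ValueError):
        return AsymptoteFit(float("nan"), float("nan"), False, float("inf"))
    return AsymptoteFit(s_hat, q_hat, True, float(np.sum(resid**2)))


def trim_estimates(
    fits,
    trim_fraction: float = DEFAULT_TRIM,
    zero_tol: float = ZERO_TOL,
) -> tuple[np.ndarray, int, int]:
    """Apply the trimming rule and return (survivors, n_removed_zero, n_removed_tails).

    Non-converged fits are counted with the S = 0 removals (both are fitting
    failures). Survivors are sorted and floor(trim_fraction * n) values are
    dropped from each end.
    """
    if not fits:
        raise ParameterError("trim_estimates requires at least one fit")
    values = []
    n_zero = 0
    for f in fits:
        if not f.converged or abs(f.s_hat) < zero_tol:
            n_zero += 1
        else:
            values.append(f.s_hat)
    if not values:
        raise EstimationError(
            f"no estimates survive trimming: {n_zero} removed as S=0/non-converged"
        )
    values = np.sort(np.asarray(values))
    k = math.floor(trim_fraction * len(values))
    survivors = values[k : len(values) - k] if k > 0 else values
    if survivors.size == 0:
        raise EstimationError(
            f"no estimates survive trimming: {n_zero} zero/non-converged, "
            f"{2 * k} trimmed from tails"
        )
    return survivors, n_zero, 2 * k


def _estimate_for_pool(
    events: EventTable,
    scope_label: str,
    n_iterations: int,
    seed,
    family: str,
    trim_fraction: float,
) -> ActiveSpeciesEstimate:
    ens = rarefy(events, n_iterations=n_iterations, seed=seed)
    fits = [fit_asymptote(tr, family=family) for tr in ens.trajectories]
    survivors, n_zero, n_tails = trim_estimates(fits, trim_fraction=trim_fraction)
    return ActiveSpeciesEstimate(
        scope=scope_label,
        s_mean=float(survivors.mean()),
        s_sd=float(survivors.std(ddof=1)) if survivors.size > 1 else 0.0,
        s_obs=ens.s_obs,
        n_events=len(events),
        n_fits_attempted=len(fits),
        n_removed_zero=n_zero,
        n_removed_tails=n_tails,
    )


def active_species(
    events: EventTable,
    scope: str = "year",
    n_iterations: int = DEFAULT_ITERATIONS,
    min_week_events: int = 5,
    seed: int | None = None,
    family: str = "exponential",
    trim_fraction: float = DEFAULT_TRIM,
) -> dict[str, ActiveSpeciesEstimate]:
    """Active-species estimates for the whole pool or per pooled week-of-year.

    ``scope="year"`` returns one estimate over all events (key "year");
    ``scope="week"`` pools events by week-of-year across years and estimates
    each week with at least ``min_week_events`` events (keys "week-<w>").
    """
    if len(events) == 0:
        raise ParameterError("active_species requires a non-empty event table")
    if scope not in ("year", "week"):
        raise ParameterError(f"scope must be 'year' or 'week', got {scope!r}")
    ss = np.random.SeedSequence(seed)
    out: dict[str, ActiveSpeciesEstimate] = {}
    if scope == "year":
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        out["year"] = _estimate_for_pool(
            events, "year", n_iterations, sub_seed, family, trim_fraction
        )
        return out
    weekly = events.by_week()
    child_seeds = ss.spawn(len(weekly))
    for (week, pool), child in zip(sorted(weekly.items()), child_seeds):
        if len(pool) < min_week_events:
            continue
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out[f"week-{week}"] = _estimate_for_pool(
            pool, f"week-{week}", n_iterations, sub_seed, family, trim_fraction
        )
    if not out:
        raise EstimationError(
            f"no week has at least {min_week_events} events; cannot estimate weekly S"
        )
    return out


def mean_weekly_estimate(weekly: dict[str, ActiveSpeciesEstimate]) -> tuple[float, float]:
    """Average-week summary: mean and SD of the per-week S_mean values."""
    vals = np.array([e.s_mean for e in weekly.values()])
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0
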