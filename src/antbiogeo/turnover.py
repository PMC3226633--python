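"""Alpha diversity per event, spatial turnover, and weekly temporal turnover.

Three complementary statistics: the mean number of species per collecting
event (alpha), the spatial turnover ratio S / alpha (how many times richer the
whole island is than a single event — compositional heterogeneity among
sites), and weekly temporal turnover measured as Bray-Curtis dissimilarity
between the species-occurrence vectors of consecutive sampled weeks. All three
use occurrence counts (events containing a species), not individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import braycurtis

from .errors import EstimationError, ParameterError
from .occurrence import EventTable


@dataclass(frozen=True)
class TurnoverReport:
    scope: str
    alpha_mean: float
    alpha_sd: float
    spatial_turnover: float | None
    temporal_turnover_mean: float | None
    temporal_turnover_sd: float | None


def alpha_per_event(events: EventTable) -> tuple[float, float]:
    """Mean and SD of distinct species per sampling event (0 for empty events)."""
    if len(events) < 1:
        raise ParameterError("alpha_per_event requires at least one event")
    richness = np.array([ev.richness for ev in events], dtype=float)
    sd = float(richness.std(ddof=1)) if richness.size > 1 else 0.0
    return float(richness.mean()), sd


def spatial_turnover(s_estimate: float, alpha_mean: float) -> float:
    """Spatial turnover ratio: S / (mean species per sampling event)."""
    if alpha_mean <= 0:
        raise ParameterError("spatial turnover undefined for alpha_mean <= 0")
    return s_estimate / alpha_mean


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(u,v)) / (sum(u)+sum(v)).

    0 when the two occurrence vectors are identical, 1 when their supports are
    disjoint. Undefined (raises) when both vectors are all zero.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError("vectors must share the same species universe")
    if (u < 0).any() or (v < 0).any():
        raise ParameterError("occurrence vectors must be non-negative")
    if u.sum() + v.sum() == 0:
        raise ParameterError("Bray-Curtis undefined for two all-zero vectors")
    return float(braycurtis(u, v))


def weekly_occurrence_vectors(events: EventTable) -> tuple[list[int], np.ndarray, tuple[str, ...]]:
    """Per-week-of-year species occurrence counts (weeks pooled across years).

    Returns (sorted sampled weeks, weeks x species count matrix, species order).
    """
    species = tuple(sorted(events.species_pool))
    idx = {sp: j for j, sp in enumerate(species)}
    weeks = events.weeks
    widx = {w: i for i, w in enumerate(weeks)}
    mat = np.zeros((len(weeks), len(species)), dtype=int)
    for ev in events:
        for sp in ev.species:
            mat[widx[ev.week], idx[sp]] += 1
    return weeks, mat, species


def weekly_temporal_turnover(events: EventTable) -> tuple[np.ndarray, float, float]:
    """Bray-Curtis between consecutive sampled weeks; returns (series, mean, sd).

    Weeks with no events are simply absent: successive *sampled* weeks are
    paired, without imputing empty weeks (the trapping design deliberately
    leaves alternate weeks unsampled).
    """
    weeks, mat, _ = weekly_occurrence_vectors(events)
    sampled = [i for i in range(len(weeks)) if mat[i].sum() > 0]
    if len(sampled) < 2:
        raise EstimationError("temporal turnover requires at least 2 sampled weeks")
    series = np.array(
        [bray_curtis(mat[a], mat[b]) for a, b in zip(sampled[:-1], sampled[1:])]
    )
    sd = float(series.std(ddof=1)) if series.size > 1 else 0.0
    return series, float(series.mean()), sd


def turnover_report(
    events: EventTable,
    s_estimate: float | None = None,
    scope: str = "park",
) -> TurnoverReport:
    """Assemble the three turnover statistics for one island or the whole park.

    Spatial turnover pairs the supplied (annual) S estimate with the annual
    alpha mean; it is omitted (None) when no estimate is given.
    """
    alpha_mean, alpha_sd = alpha_per_event(events)
    spatial = None
    if s_estimate is not None and alpha_mean > 0:
        spatial = spatial_turnover(s_estimate, alpha_mean)
    try:
        _, t_mean, t_sd = weekly_temporal_turnover(events)
    except EstimationError:
        t_mean = t_sd = None
    return TurnoverReport(scope, alpha_mean, alpha_sd, spatial, t_mean, t_sd)
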