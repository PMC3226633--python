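"""Sample-based rarefaction by event resampling, with the Chao II estimator.

Rarefaction here is occurrence-based: each iteration draws a uniform random
permutation of the collecting events (sampling without replacement) and
accumulates the number of distinct species, so a species counts once per event
regardless of how many individuals were collected. The average over iterations
estimates the expected species count at each sampling effort, and an empirical
percentile envelope provides the confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .occurrence import EventTable

DEFAULT_ITERATIONS = 1000


@dataclass
class RarefactionEnsemble:
    """Per-iteration species-accumulation trajectories.

    ``trajectories`` has shape (n_iterations, n_events); entry (i, n-1) is the
    number of distinct species after the first n events of permutation i.
    """

    trajectories: np.ndarray
    species: tuple[str, ...]
    rng_seed: int | None

    @property
    def n_iterations(self) -> int:
        return self.trajectories.shape[0]

    @property
    def n_events(self) -> int:
        return self.trajectories.shape[1]

    @property
    def s_obs(self) -> int:
        return len(self.species)


@dataclass
class RarefactionCurve:
    """Mean accumulation curve with an empirical percentile envelope."""

    n: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"n_events": self.n, "mean": self.mean, "lower": self.lower, "upper": self.upper}
        )


def incidence_matrix(events: EventTable) -> tuple[np.ndarray, tuple[str, ...]]:
    """Boolean events x species incidence matrix and the species ordering."""
    species = tuple(sorted(events.species_pool))
    idx = {sp: j for j, sp in enumerate(species)}
    m = np.zeros((len(events), len(species)), dtype=bool)
    for i, ev in enumerate(events):
        for sp in ev.species:
            m[i, idx[sp]] = True
    return m, species


def rarefy(
    events: EventTable,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
) -> RarefactionEnsemble:
    """Build a rarefaction ensemble by permuting collecting events."""
    if n_iterations < 1:
        raise ParameterError("n_iterations must be >= 1")
    if len(events) < 1:
        raise ParameterError("rarefaction requires at least one event")
    inc, species = incidence_matrix(events)
    n_events = inc.shape[0]
    rng = np.random.default_rng(seed)
    traj = np.empty((n_iterations, n_events), dtype=np.int64)
    for i in range(n_iterations):
        order = rng.permutation(n_events)
        seen = np.cumsum(inc[order], axis=0) > 0
        traj[i] = seen.sum(axis=1)
    return RarefactionEnsemble(trajectories=traj, species=species, rng_seed=seed)


def curve_summary(ensemble: RarefactionEnsemble, level: float = 0.95) -> RarefactionCurve:
    """Mean curve and empirical ((1-level)/2, 1-(1-level)/2) percentile envelope."""
    if not 0 < level < 1:
        raise ParameterError("confidence level must be in (0, 1)")
    traj = ensemble.trajectories
    tail = (1 - level) / 2 * 100
    return RarefactionCurve(
        n=np.arange(1, ensemble.n_events + 1),
        mean=traj.mean(axis=0),
        lower=np.percentile(traj, tail, axis=0),
        upper=np.percentile(traj, 100 - tail, axis=0),
        level=level,
    )


@dataclass(frozen=True)
class Chao2Estimate:
    estimate: float
    se: float
    s_obs: int
    q1: int
    q2: int
    m: int


def chao2(events: EventTable) -> Chao2Estimate:
    """Bias-corrected Chao II incidence estimator with its classical variance.

    With m events, S_obs observed species and Q1/Q2 species found in exactly
    one/two events:

        S_chao2 = S_obs + ((m-1)/m) * Q1*(Q1-1) / (2*(Q2+1))

    The bias-corrected form stays defined at Q2 = 0, which matters on small
    weekly event pools.
    """
    if len(events) < 2:
        raise ParameterError("Chao II requires at least 2 events")
    inc, species = incidence_matrix(events)
    freqs = inc.sum(axis=0)
    s_obs = len(species)
    m = inc.shape[0]
    q1 = int((freqs == 1).sum())
    q2 = int((freqs == 2).sum())
    a = (m - 1) / m
    est = s_obs + a * q1 * (q1 - 1) / (2 * (q2 + 1))
    var = (
        a * q1 * (q1 - 1) / (2 * (q2 + 1))
        + a**2 * q1 * (2 * q1 - 1) ** 2 / (4 * (q2 + 1) ** 2)
        + a**2 * q1**2 * q2 * (q1 - 1) ** 2 / (4 * (q2 + 1) ** 4)
    )
    return Chao2Estimate(float(est), float(np.sqrt(var)), s_obs, q1, q2, m)
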