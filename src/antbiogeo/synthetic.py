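"""Synthetic island-park community generator.

Generates event-level incidence data with the statistical structure the
analysis pipeline assumes, so every downstream stage can be exercised and
validated against a known truth without the field dataset:

* island species pools scale with geography, S = round(c * area^z * e^(-k*iso))
  — a power law in area with exponential isolation decay (two interpretable
  parameters; any monotone rule supports sign-recovery tests);
* every pool species resides on its island all season (colony dispersal is far
  slower than a season), but is only intermittently *active*: activity is a
  two-state (active/dormant) persistence chain per (species, plot), keyed by
  week-of-year and shared across years, which is what produces constant weekly
  richness with changing identities;
* collecting events detect each plot-active species independently with a
  per-method detection probability; abundance is 1 + geometric noise purely to
  exercise I/O (all analysis is occurrence-based).

The per-plot activity rate is calibrated so that the expected fraction of the
island pool active in any one week matches ``weekly_active_fraction``:
a = 1 - (1 - f)^(1/n_sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .occurrence import EventTable, SamplingEvent, _event_id

#: Table-style default geography for a ten-island park (name, km^2, km).
DEFAULT_ISLANDS = (
    ("Bumpkin", 0.12, 0.64),
    ("Calf", 0.07, 3.29),
    ("Grape", 0.22, 0.47),
    ("Great Brewster", 0.08, 2.36),
    ("Langlee", 0.02, 0.52),
    ("Ragged", 0.01, 0.32),
    ("Snake", 0.03, 0.35),
    ("Spectacle", 0.35, 1.92),
    ("Thompson", 0.54, 0.51),
    ("Worlds End", 1.08, 0.00),
)

DEFAULT_DOMINANTS = (
    "Aphaenogaster rudis Complex",
    "Myrmica rubra",
    "Tetramorium caespitum",
)


@dataclass(frozen=True)
class SimulationConfig:
    islands: tuple[tuple[str, float, float], ...] = DEFAULT_ISLANDS
    #: (c, z, k) of S_island = round(c * area^z * exp(-k * isolation))
    pool_size_rule: tuple[float, float, float] = (38.0, 0.08, 0.12)
    years: tuple[int, ...] = (2005, 2006, 2007, 2008, 2009)
    #: sampled weeks-of-year (biweekly cadence, early May - late October)
    weeks: tuple[int, ...] = tuple(range(18, 45, 2))
    sites_per_island: int = 3
    weekly_active_fraction: float = 0.55
    activity_persistence: float = 0.7
    step_weeks: int = 2
    detection_prob: tuple[tuple[str, float], ...] = (
        ("pitfall", 0.46),
        ("malaise", 0.42),
        ("bait", 0.58),
        ("hand", 0.65),
    )
    #: half-range of the weekly trapping-efficiency multiplier (uniform on
    #: 1 +/- range, keyed by island and week-of-year): weather and season make
    #: some collecting weeks systematically better than others
    weekly_detection_range: float = 0.4
    events_per_island_week: int = 2
    dominant_species: tuple[str, ...] = DEFAULT_DOMINANTS
    #: multiplier on the dominants' island-level weekly active fraction
    dominant_boost: float = 1.5
    #: Beta concentration of the per-species activity spread (mean stays at
    #: weekly_active_fraction); lower = more skew between common and rare species
    activity_concentration: float = 3.0
    #: guarantee each species one activity-burst week (see simulate_park)
    phenology_burst: bool = True
    #: 0 = undisturbed; > 0 shifts plot dynamics toward the dominant species
    disturbance: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.sites_per_island < 1 or not self.weeks:
            raise ConfigurationError("need at least one site and one sampling week")
        if not self.years:
            raise ConfigurationError("need at least one sampling year")
        if not 0 < self.weekly_active_fraction <= 1:
            raise ConfigurationError("weekly_active_fraction must be in (0, 1]")
        probs = [self.activity_persistence, self.disturbance] + [
            p for _, p in self.detection_prob
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if not 0 <= self.weekly_detection_range < 1:
            raise ConfigurationError("weekly_detection_range must be in [0, 1)")
        if self.events_per_island_week > self.sites_per_island:
            raise ConfigurationError(
                "events_per_island_week cannot exceed sites_per_island "
                "(one event per site per week)"
            )
        if any(self.pool_size(a, i) < 1 for _, a, i in self.islands):
            raise ConfigurationError("pool sizes must be >= 1")

    def pool_size(self, area_km2: float, isolation_km: float) -> int:
        c, z, k = self.pool_size_rule
        return max(1, round(c * area_km2**z * np.exp(-k * isolation_km)))


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated park."""

    pools: dict[str, tuple[str, ...]]
    #: (island, week) -> species truly active at >= 1 plot that week
    weekly_active: dict[tuple[str, int], frozenset[str]]
    #: (island, site, week) -> species active at that plot that week
    plot_active: dict[tuple[str, str, int], frozenset[str]]
    config: SimulationConfig

    def weekly_fraction(self) -> float:
        """Season-mean |weekly active| / |pool| across islands and weeks."""
        fracs = [
            len(act) / len(self.pools[isl])
            for (isl, _), act in self.weekly_active.items()
        ]
        return float(np.mean(fracs))


def default_config() -> SimulationConfig:
    """The ten-island default configuration (pure: identical on every call)."""
    return SimulationConfig()


def _species_names(n: int) -> tuple[str, ...]:
    """Master species list: dominants first, then numbered residents."""
    names = list(DEFAULT_DOMINANTS)
    i = 1
    while len(names) < n:
        names.append(f"resident_{i:03d}")
        i += 1
    return tuple(names[:n])


def simulate_park(config: SimulationConfig) -> tuple[EventTable, SyntheticTruth]:
    """Simulate a season of event-level sampling across the configured park.

    Identical seeds give identical output. Activity realizations are keyed by
    week-of-year and shared across years (the resident pool and its weekly
    activity schedule belong to the island; years differ only in which sites
    were visited and what each event detected).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    max_pool = max(config.pool_size(a, i) for _, a, i in config.islands)
    master = _species_names(max_pool)
    n_dom = sum(sp in config.dominant_species for sp in master)

    f = config.weekly_active_fraction
    n_sites = config.sites_per_island
    p = config.activity_persistence
    d = config.disturbance

    methods = tuple(m for m, _ in config.detection_prob)
    det = dict(config.detection_prob)

    pools: dict[str, tuple[str, ...]] = {}
    weekly_active: dict[tuple[str, int], frozenset[str]] = {}
    plot_active: dict[tuple[str, str, int], frozenset[str]] = {}
    events: list[SamplingEvent] = []

    for island, area, iso in config.islands:
        pool = master[: config.pool_size(area, iso)]
        pools[island] = pool
        sites = tuple(f"plot{s:02d}" for s in range(1, n_sites + 1))
        n_sp = len(pool)

        # per-species island-level weekly fractions: Beta-spread around the
        # target mean, so occurrence frequencies are right-skewed as in real
        # ant incidence data (a few common species, many occasional ones)
        kappa = config.activity_concentration
        is_dom = np.array([sp in config.dominant_species for sp in pool])
        f_dom = min(0.98, f * config.dominant_boost)
        # non-dominant mean compensates the dominants' boost so the island-wide
        # mean weekly fraction stays at the configured target
        f_nd = (f * n_sp - f_dom * is_dom.sum()) / max(n_sp - is_dom.sum(), 1)
        # per-species fractions on [f_lo, f_hi]: the floor keeps every resident
        # collectible within a season (no species is dormant all year), the
        # Beta shape keeps the incidence distribution right-skewed
        if f >= 1.0:
            f_i = np.ones(n_sp)  # degenerate limit: everything always active
        else:
            f_lo, f_hi = 0.25, 0.98
            f_nd = min(max(f_nd, f_lo + 0.05), f_hi - 0.05)
            # deflate for the burst-week overlay below, which adds (1 - f)/W
            # of expected presence per species-week, keeping the mean at f_nd
            n_weeks = len(config.weeks)
            if config.phenology_burst:
                f_nd = max(f_lo + 0.01, (f_nd - 1.0 / n_weeks) / (1.0 - 1.0 / n_weeks))
            m = (f_nd - f_lo) / (f_hi - f_lo)
            f_i = f_lo + (f_hi - f_lo) * rng.beta(m * kappa, (1.0 - m) * kappa, size=n_sp)
            f_i[is_dom] = f_dom
        # plot-level activity rate a_i gives island fraction f_i = 1-(1-a_i)^n_sites
        a_i = 1.0 - (1.0 - f_i) ** (1.0 / n_sites)

        # disturbance shifts plot dynamics toward dominants: dominants persist
        # and recruit more, residents recruit less
        persist = np.full(n_sp, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            recruit = np.where(a_i >= 1.0, 1.0, a_i * (1.0 - persist) / (1.0 - a_i))
        if d > 0:
            for j, sp in enumerate(pool):
                if sp in config.dominant_species:
                    persist[j] = p + (1.0 - p) * d
                    recruit[j] = min(1.0, recruit[j] * (1.0 + 2.0 * d))
                else:
                    recruit[j] = recruit[j] * (1.0 - d)
        recruit = np.clip(recruit, 0.0, 1.0)

        # weekly trapping-efficiency multipliers, keyed by week-of-year
        r = config.weekly_detection_range
        week_eff = 1.0 - r + 2.0 * r * rng.random(len(config.weeks))

        # one guaranteed activity-burst week per species (phenology anchor):
        # every resident colony sends out foragers at some point in the season
        burst_week = rng.integers(len(config.weeks), size=n_sp)
        burst_site = rng.integers(n_sites, size=n_sp)

        # activity chains: (species, site) over the week-of-year grid
        active = rng.random((n_sp, n_sites)) < a_i[:, None]
        for w_idx, week in enumerate(config.weeks):
            if w_idx > 0:
                u = rng.random((n_sp, n_sites))
                active = np.where(active, u < persist[:, None], u < recruit[:, None])
            # burst overlay: presence this week without feeding the chain
            shown = active.copy()
            if config.phenology_burst:
                hit = burst_week == w_idx
                shown[hit, burst_site[hit]] = True
            for s_idx, site in enumerate(sites):
                plot_active[(island, site, week)] = frozenset(
                    pool[j] for j in np.flatnonzero(shown[:, s_idx])
                )
            weekly_active[(island, week)] = frozenset(
                pool[j] for j in np.flatnonzero(shown.any(axis=1))
            )

            for year in config.years:
                visited = rng.choice(n_sites, size=config.events_per_island_week, replace=False)
                for e_idx, s_idx in enumerate(visited):
                    site = sites[s_idx]
                    method = methods[(w_idx + e_idx) % len(methods)]
                    present = np.flatnonzero(shown[:, s_idx])
                    p_det = min(1.0, det[method] * week_eff[w_idx])
                    detected = present[rng.random(present.size) < p_det]
                    counts = {pool[j]: int(rng.geometric(0.5)) for j in detected}
                    events.append(
                        SamplingEvent(
                            event_id=_event_id(island, site, year, week, method),
                            island=island,
                            site=site,
                            year=year,
                            week=week,
                            method=method,
                            counts=counts,
                            habitat="unknown",
                        )
                    )

    lo = min(min(config.weeks), 18)
    hi = max(max(config.weeks), 44)
    table = EventTable(events, week_window=(lo, hi))
    return table, SyntheticTruth(
        pools=pools, weekly_active=weekly_active, plot_active=plot_active, config=config
    )


def simulate_state_chain(
    transition: np.ndarray,
    state_species: tuple[frozenset[str] | None, ...],
    n_plots: int,
    n_steps: int,
    seed: int | None = None,
    island: str = "SimIsland",
    year: int = 2005,
    start_week: int = 18,
    step_weeks: int = 2,
    method: str = "pitfall",
) -> EventTable:
    """Emit events from a known per-plot state chain (for recovery checks).

    Each plot runs an independent Markov chain over the given states, starting
    from the chain's uniform-start distribution at step 0; each plot-step
    produces one perfectly detecting event containing exactly that state's
    species (``None`` means a catch-all state represented by a sentinel
    species so projections map it to 'other').
    """
    p = np.asarray(transition, dtype=float)
    k = p.shape[0]
    if p.shape != (k, k) or not np.allclose(p.sum(axis=1), 1.0):
        raise ConfigurationError("transition matrix must be square and row-stochastic")
    if n_plots < 1 or n_steps < 2:
        raise ConfigurationError("need at least 1 plot and 2 steps")
    rng = np.random.default_rng(seed)
    specs = [
        s if s is not None else frozenset({"other_resident"}) for s in state_species
    ]
    events = []
    cum = p.cumsum(axis=1)
    for plot in range(n_plots):
        site = f"plot{plot:04d}"
        state = int(rng.integers(k))
        for t in range(n_steps):
            week = start_week + t * step_weeks
            counts = {sp: 1 for sp in specs[state]}
            events.append(
                SamplingEvent(
                    event_id=_event_id(island, site, year, week, method),
                    island=island,
                    site=site,
                    year=year,
                    week=week,
                    method=method,
                    counts=counts,
                )
            )
            if t < n_steps - 1:
                state = int(np.searchsorted(cum[state], rng.random(), side="right"))
    lo = min(start_week, 18)
    hi = max(start_week + (n_steps - 1) * step_weeks, 44)
    return EventTable(events, week_window=(lo, hi))
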