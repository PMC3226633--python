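"""Markov model of plot-level assemblage dynamics.

Each sampling plot yields a time series of *assemblages* (the set of species
inferred present during one roughly two-week step). Presence gaps are filled
by a capture-recapture rule (a species seen before and after a gap is assumed
present throughout), very rare species are trimmed to the set covering 95% of
collection events, statistically indistinguishable assemblages are merged by
species-set intersection (G-test), and transitions between assemblage states
are tabulated into a count matrix under a deliberate multi-counting
convention: a step from AB to BC counts A->B, A->BC, B->B, B->BC, AB->B,
AB->BC and so on for every state contained in the source and target. The
reduced row-stochastic matrix's left eigenvector at eigenvalue 1 — the stable
state distribution — approximates the relative time each community state
persists. Because states are not mutually exclusive under multi-counting, the
stable state distribution is not a probability vector, only a relative
persistence measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2

from .errors import EstimationError, FormatError, MappingError, ParameterError
from .occurrence import EventTable

NONE_LABEL = "none"
OTHER_LABEL = "other"


def assemblage_label(species: frozenset[str] | None) -> str:
    """Canonical label: sorted species joined by '+', 'none' for the empty set."""
    if species is None:
        return OTHER_LABEL
    if not species:
        return NONE_LABEL
    return "+".join(sorted(species))


@dataclass
class PlotSeries:
    """Assemblage time series at one plot (one island/site/year)."""

    plot_id: str
    steps: tuple[int, ...]
    assemblages: tuple[frozenset[str], ...]
    sampled: tuple[bool, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.steps, self.steps[1:])):
            raise ParameterError(f"plot {self.plot_id}: steps must be strictly increasing")
        if not (len(self.steps) == len(self.assemblages) == len(self.sampled)):
            raise ParameterError(f"plot {self.plot_id}: field lengths differ")

    def observable(self, i: int) -> bool:
        """A step contributes transitions if it was sampled or has inferred presence."""
        return self.sampled[i] or bool(self.assemblages[i])


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    p: float


@dataclass
class TransitionCountMatrix:
    """Square transition counts between assemblage states."""

    labels: tuple[str, ...]
    species_sets: tuple[frozenset[str] | None, ...]
    counts: np.ndarray
    n_transitions: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ParameterError("transition count matrix must be square over the states")
        if (self.counts < 0).any():
            raise ParameterError("transition counts must be non-negative")
        self.n_transitions = int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class StableStateDistribution:
    labels: tuple[str, ...]
    pi: np.ndarray
    closed_classes: tuple[tuple[int, ...], ...]
    class_weights: tuple[float, ...]


def build_plot_series(
    events: EventTable,
    step_weeks: int = 2,
    retained: frozenset[str] | None = None,
) -> list[PlotSeries]:
    """Bin each plot-year's events into sequential steps of ``step_weeks`` weeks.

    The assemblage at a step is the union of species observed in the bin
    (restricted to ``retained`` when given); bins between the first and last
    sampled bin with no events are kept as unsampled 'none' steps so that gap
    filling can restore presence across them.
    """
    if not len(events):
        raise FormatError("no events to build plot series from")
    base_week = events.week_window[0]
    groups: dict[tuple, dict[int, set[str]]] = {}
    for ev in events:
        if not str(ev.site):
            raise FormatError("events must carry plot (site) identifiers")
        key = (ev.island, ev.site, ev.year)
        b = (ev.week - base_week) // step_weeks
        bins = groups.setdefault(key, {})
        sp = set(ev.species)
        if retained is not None:
            sp &= retained
        bins.setdefault(b, set()).update(sp)
    out = []
    for (island, site, year), bins in sorted(groups.items()):
        lo, hi = min(bins), max(bins)
        steps = tuple(range(lo, hi + 1))
        out.append(
            PlotSeries(
                plot_id=f"{island}|{site}|{year}",
                steps=steps,
                assemblages=tuple(frozenset(bins.get(b, set())) for b in steps),
                sampled=tuple(b in bins for b in steps),
            )
        )
    return out


def fill_gaps(series: PlotSeries) -> PlotSeries:
    """Capture-recapture gap filling: presence spans first to last detection.

    Idempotent, and never removes a presence. Sampling flags are unchanged:
    the rule restores species presence, not sampling coverage.
    """
    n = len(series.steps)
    filled = [set(a) for a in series.assemblages]
    species = set().union(*series.assemblages) if series.assemblages else set()
    for sp in species:
        hits = [i for i in range(n) if sp in series.assemblages[i]]
        for i in range(hits[0], hits[-1] + 1):
            filled[i].add(sp)
    return replace(series, assemblages=tuple(frozenset(s) for s in filled))


def trim_rare(events: EventTable, coverage: float = 0.95) -> frozenset[str]:
    """Most common species covering ``coverage`` of collection-event occurrences.

    Species are ranked by occurrence count (events containing them) and the
    smallest prefix whose cumulative share reaches the coverage is retained;
    species tied with the last retained count are all kept.
    """
    if not 0 < coverage <= 1:
        raise ParameterError("coverage must be in (0, 1]")
    counts: dict[str, int] = {}
    for ev in events:
        for sp in ev.species:
            counts[sp] = counts.get(sp, 0) + 1
    if not counts:
        raise ParameterError("trim_rare requires at least one occurrence")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    kept: list[str] = []
    cum = 0
    for sp, c in ranked:
        kept.append(sp)
        cum += c
        if cum / total >= coverage:
            boundary = c
            for sp2, c2 in ranked[len(kept):]:
                if c2 == boundary:
                    kept.append(sp2)
                else:
                    break
            break
    return frozenset(kept)


def g_test(table) -> GTestResult:
    """G-test of independence: G = 2 * sum O * ln(O/E), df = (r-1)(c-1).

    All-zero rows and columns are dropped first; 0 * ln(0) is taken as 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ParameterError("g_test expects a 2-way table")
    if (obs < 0).any():
        raise ParameterError("g_test requires non-negative counts")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0] if obs.size else obs
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise EstimationError("table degenerate after removing all-zero lines")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = float(2 * terms.sum())
    g = max(g, 0.0)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return GTestResult(g=g, df=df, p=float(chi2.sf(g, df)))


def _pair_p(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """p-value for distinguishability of two count profiles; 1.0 when degenerate."""
    table = np.stack([profile_a, profile_b])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 1.0
    return g_test(table).p


def _mergeable(p: float, alpha: float, merge_rule: str) -> bool:
    if merge_rule == "standard":
        return p > alpha
    if merge_rule == "as_printed":
        return p <= alpha
    raise ParameterError(f"unknown merge_rule {merge_rule!r}")


def transition_pairs(series_list) -> list[tuple[frozenset[str], frozenset[str]]]:
    """All (source, target) assemblage pairs between consecutive observable steps."""
    pairs = []
    for s in series_list:
        for i in range(len(s.steps) - 1):
            if s.observable(i) and s.observable(i + 1):
                pairs.append((s.assemblages[i], s.assemblages[i + 1]))
    return pairs


@dataclass
class AssemblageClasses:
    """Result of merging observed assemblages into classes."""

    species_sets: tuple[frozenset[str], ...]
    members: tuple[tuple[frozenset[str], ...], ...]
    mapping: dict[frozenset[str], int]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(assemblage_label(s) for s in self.species_sets)


def merge_indistinguishable(
    series_list,
    alpha: float = 0.05,
    profile: str = "transitions",
    merge_rule: str = "standard",
) -> AssemblageClasses:
    """Merge assemblages whose profiles a G-test cannot tell apart.

    Each observed (non-empty) assemblage starts as its own class. Pairwise
    profiles are compared with a G-test; a pair the test fails to reject at
    ``alpha`` is merged into the *intersection* of the two species sets (an
    empty intersection becomes the distinguished 'none' class). Profiles are
    transition-target counts by default, or per-plot occurrence counts with
    ``profile="occurrence"``. Merging repeats to a fixed point, always taking
    the most frequent mergeable pair first with a lexicographic tie-break, so
    the result is deterministic.
    """
    if profile not in ("transitions", "occurrence"):
        raise ParameterError(f"unknown profile {profile!r}")
    observed: dict[frozenset[str], int] = {}
    for s in series_list:
        for i, a in enumerate(s.assemblages):
            if a and s.observable(i):
                observed[a] = observed.get(a, 0) + 1
    if len(observed) < 2:
        sets = tuple(observed)
        return AssemblageClasses(sets, tuple((a,) for a in sets), {a: i for i, a in enumerate(sets)})

    obs_list = sorted(observed, key=assemblage_label)
    obs_idx = {a: i for i, a in enumerate(obs_list)}
    n_obs = len(obs_list)

    # base profile counts per observed assemblage
    if profile == "transitions":
        # columns: target observed assemblages + one trailing 'none' column
        base = np.zeros((n_obs, n_obs + 1), dtype=np.int64)
        for src, dst in transition_pairs(series_list):
            if not src:
                continue
            base[obs_idx[src], obs_idx.get(dst, n_obs)] += 1
    else:
        plots = {s.plot_id: i for i, s in enumerate(series_list)}
        base = np.zeros((n_obs, len(plots)), dtype=np.int64)
        for s in series_list:
            for i, a in enumerate(s.assemblages):
                if a and s.observable(i):
                    base[obs_idx[a], plots[s.plot_id]] += 1

    # class bookkeeping: each observed assemblage starts as its own class
    classes = [
        {"species": a, "members": {a}, "freq": observed[a]} for a in obs_list
    ]

    def class_profiles() -> np.ndarray:
        k = len(classes)
        member_of = np.empty(n_obs, dtype=np.int64)
        for ci, c in enumerate(classes):
            for a in c["members"]:
                member_of[obs_idx[a]] = ci
        rows = np.zeros((k, base.shape[1]), dtype=np.int64)
        np.add.at(rows, member_of, base)
        if profile == "transitions":
            prof = np.zeros((k, k + 1), dtype=np.int64)
            np.add.at(prof.T[:k], member_of, rows[:, :n_obs].T)
            prof[:, k] = rows[:, n_obs]
            return prof
        return rows

    merged_any = True
    while merged_any and len(classes) > 1:
        merged_any = False
        prof = class_profiles()
        order = sorted(
            (
                (-(classes[i]["freq"] + classes[j]["freq"]),
                 assemblage_label(classes[i]["species"]),
                 assemblage_label(classes[j]["species"]), i, j)
                for i in range(len(classes))
                for j in range(i + 1, len(classes))
            )
        )
        # most-frequent pair first: merge the first pair the G-test cannot
        # tell apart, then rebuild profiles and start over
        for _, _, _, i, j in order:
            if _mergeable(_pair_p(prof[i], prof[j]), alpha, merge_rule):
                merged = {
                    "species": classes[i]["species"] & classes[j]["species"],
                    "members": classes[i]["members"] | classes[j]["members"],
                    "freq": classes[i]["freq"] + classes[j]["freq"],
                }
                rest = [c for k_, c in enumerate(classes) if k_ not in (i, j)]
                for c in rest:  # coalesce with an equal species set if present
                    if c["species"] == merged["species"]:
                        c["members"] |= merged["members"]
                        c["freq"] += merged["freq"]
                        break
                else:
                    rest.append(merged)
                classes = rest
                merged_any = True
                break

    classes.sort(key=lambda c: assemblage_label(c["species"]))
    mapping = {a: ci for ci, c in enumerate(classes) for a in c["members"]}
    return AssemblageClasses(
        species_sets=tuple(c["species"] for c in classes),
        members=tuple(tuple(sorted(c["members"], key=assemblage_label)) for c in classes),
        mapping=mapping,
    )


def _states_in(
    assemblage: frozenset[str],
    species_sets,
    none_index: int | None,
) -> list[int]:
    """Indices of the states contained in an observed assemblage."""
    if not assemblage:
        return [none_index] if none_index is not None else []
    found = [
        i for i, s in enumerate(species_sets) if s is not None and s and s <= assemblage
    ]
    return found


def tabulate_transitions(series_list, states: AssemblageClasses | list) -> TransitionCountMatrix:
    """Count transitions under the multi-counting convention.

    For each consecutive observable step pair, one count is added from *every*
    state contained in the source assemblage to *every* state contained in the
    target (AB -> BC contributes A->B, A->BC, B->B, ... when those states
    exist). An empty assemblage maps to the distinguished 'none' state, which
    is added when empty assemblages occur.
    """
    mapping: dict[frozenset[str], int] = {}
    if isinstance(states, AssemblageClasses):
        species_sets = list(states.species_sets)
        mapping = dict(states.mapping)
    else:
        species_sets = [frozenset(s) if s is not None else None for s in states]
    pairs = transition_pairs(series_list)
    needs_none = any((not a) or (not b) for a, b in pairs)
    none_index = next((i for i, s in enumerate(species_sets) if s == frozenset()), None)
    if needs_none and none_index is None:
        species_sets.append(frozenset())
        none_index = len(species_sets) - 1
    k = len(species_sets)
    counts = np.zeros((k, k), dtype=np.int64)

    def states_of(a: frozenset[str]) -> list[int]:
        found = set(_states_in(a, species_sets, none_index))
        if a and a in mapping:  # the class the assemblage belongs to
            found.add(mapping[a])
        return sorted(found)

    for a, b in pairs:
        src = states_of(a)
        dst = states_of(b)
        if a and not src:
            raise MappingError(f"no state covers observed assemblage {assemblage_label(a)!r}")
        if b and not dst:
            raise MappingError(f"no state covers observed assemblage {assemblage_label(b)!r}")
        for i in src:
            for j in dst:
                counts[i, j] += 1
    labels = tuple(assemblage_label(s) for s in species_sets)
    return TransitionCountMatrix(labels=labels, species_sets=tuple(species_sets), counts=counts)


def reduce_states(
    matrix: TransitionCountMatrix,
    alpha: float = 0.05,
    merge_rule: str = "standard",
) -> TransitionCountMatrix:
    """Bossert-style reduction: merge states with indistinguishable columns.

    Repeatedly, the pair of states whose column count-vectors give the largest
    G-test p-value above the merge threshold is combined by species-set
    intersection (rows and columns summed), until every remaining pair is
    distinguishable. The reduced matrix generates sequences statistically
    indistinguishable from the original.
    """
    labels = list(matrix.labels)
    species = list(matrix.species_sets)
    counts = matrix.counts.copy()
    while len(labels) > 1:
        k = len(labels)
        best = None  # (p, tie-break labels, i, j)
        for i in range(k):
            for j in range(i + 1, k):
                p = _pair_p(counts[:, i], counts[:, j])
                if _mergeable(p, alpha, merge_rule):
                    key = (-p, labels[i], labels[j])
                    if best is None or key < best[0]:
                        best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        si, sj = species[i], species[j]
        if si is None or sj is None:
            new_sp = None  # merging into the catch-all keeps it a catch-all
        else:
            new_sp = si & sj
        new_counts = np.delete(np.delete(counts, j, axis=0), j, axis=1)
        new_counts[:, i] = np.delete(counts[:, i] + counts[:, j], j)
        new_counts[i, :] = np.delete(counts[i, :] + counts[j, :], j)
        new_counts[i, i] = counts[i, i] + counts[i, j] + counts[j, i] + counts[j, j]
        labels.pop(j)
        species.pop(j)
        counts = new_counts
        species[i] = new_sp
        labels[i] = assemblage_label(new_sp)
        # coalesce a species-set collision with another existing state
        for m in range(len(labels)):
            if m != i and species[m] == species[i]:
                a, b = min(i, m), max(i, m)
                merged = np.delete(np.delete(counts, b, axis=0), b, axis=1)
                merged[:, a] = np.delete(counts[:, a] + counts[:, b], b)
                merged[a, :] = np.delete(counts[a, :] + counts[b, :], b)
                merged[a, a] = counts[a, a] + counts[a, b] + counts[b, a] + counts[b, b]
                labels.pop(b)
                species.pop(b)
                counts = merged
                break
    return TransitionCountMatrix(
        labels=tuple(labels), species_sets=tuple(species), counts=counts
    )


def to_stochastic(matrix: TransitionCountMatrix) -> np.ndarray:
    """Row-normalize transition counts; zero rows become self-absorbing."""
    counts = matrix.counts.astype(float)
    row = counts.sum(axis=1)
    p = np.zeros_like(counts)
    for i in range(len(row)):
        if row[i] == 0:
            warnings.warn(
                f"state {matrix.labels[i]!r} has no outgoing transitions; made self-absorbing",
                stacklevel=2,
            )
            p[i, i] = 1.0
        else:
            p[i] = counts[i] / row[i]
    return p


def stable_state(
    p: np.ndarray,
    labels: tuple[str, ...] | None = None,
    tol: float = 1e-9,
) -> StableStateDistribution:
    """Left eigenvector of a row-stochastic matrix at eigenvalue 1.

    For a reducible chain the stationary distribution of each closed
    communicating class is computed separately and the classes are combined
    with reachability weights (probability of absorption from a uniform
    start). The result is non-negative, sums to 1 and satisfies pi @ P = pi.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ParameterError("stochastic matrix must be square")
    k = p.shape[0]
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ParameterError("matrix rows must sum to 1")
    if (p < -tol).any():
        raise ParameterError("matrix entries must be non-negative")
    if labels is None:
        labels = tuple(str(i) for i in range(k))

    n_comp, comp = connected_components(p > tol, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        idx = np.where(comp == c)[0]
        if np.allclose(p[np.ix_(idx, idx)].sum(axis=1), 1.0, atol=1e-8):
            closed.append(tuple(int(i) for i in idx))
    closed.sort()

    def _stationary(sub: np.ndarray) -> np.ndarray:
        m = sub.shape[0]
        a = np.vstack([sub.T - np.eye(m), np.ones(m)])
        b = np.zeros(m + 1)
        b[-1] = 1.0
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        sol = np.clip(sol, 0.0, None)
        return sol / sol.sum()

    # absorption weights from a uniform start over all states
    closed_states = sorted(i for cls in closed for i in cls)
    transient = [i for i in range(k) if i not in closed_states]
    weights = []
    if transient:
        q = p[np.ix_(transient, transient)]
        fundamental = np.linalg.solve(np.eye(len(transient)) - q, np.eye(len(transient)))
    for cls in closed:
        w = len(cls) / k
        if transient:
            r = p[np.ix_(transient, list(cls))].sum(axis=1)
            absorb = fundamental @ r
            w += absorb.sum() / k
        weights.append(w)
    weights = np.asarray(weights)
    weights = weights / weights.sum()

    pi = np.zeros(k)
    for cls, w in zip(closed, weights):
        idx = list(cls)
        pi[idx] = w * _stationary(p[np.ix_(idx, idx)])
    return StableStateDistribution(
        labels=labels,
        pi=pi,
        closed_classes=tuple(closed),
        class_weights=tuple(float(w) for w in weights),
    )


DEFAULT_DOMINANTS = (
    "Aphaenogaster rudis Complex",
    "Myrmica rubra",
    "Tetramorium caespitum",
)


def four_state_projection(
    series_list,
    dominants: tuple[str, str, str] = DEFAULT_DOMINANTS,
) -> tuple[TransitionCountMatrix, np.ndarray, StableStateDistribution]:
    """Project assemblages onto three dominant species plus an 'other' state.

    Each observed assemblage maps to the dominant singletons it contains; any
    non-dominant content (including an empty assemblage) maps to the fourth
    'other' state. Transitions are tabulated under the multi-counting
    convention, then the stochastic matrix and stable state distribution are
    returned.
    """
    dom = tuple(dominants)
    observed_species = set()
    for s in series_list:
        for a in s.assemblages:
            observed_species |= a
    for d in dom:
        if d not in observed_species:
            warnings.warn(f"dominant species {d!r} absent from the data", stacklevel=2)

    labels = tuple(list(dom) + [OTHER_LABEL])
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)

    def states_of(a: frozenset[str]) -> list[int]:
        idx = [i for i, d in enumerate(dom) if d in a]
        if (a - set(dom)) or not idx:
            idx.append(k - 1)
        return idx

    for a, b in transition_pairs(series_list):
        for i in states_of(a):
            for j in states_of(b):
                counts[i, j] += 1
    tcm = TransitionCountMatrix(
        labels=labels,
        species_sets=tuple([frozenset({d}) for d in dom] + [None]),
        counts=counts,
    )
    # stationary mass only over states that actually occur; an unobserved
    # dominant keeps pi = 0 instead of becoming a spurious absorbing state
    observed = (counts.sum(axis=0) + counts.sum(axis=1)) > 0
    p = np.eye(k)
    pi_full = np.zeros(k)
    closed: tuple = ()
    weights: tuple = ()
    if observed.any():
        idx = np.flatnonzero(observed)
        sub = TransitionCountMatrix(
            labels=tuple(labels[i] for i in idx),
            species_sets=tuple(tcm.species_sets[i] for i in idx),
            counts=counts[np.ix_(idx, idx)],
        )
        p_sub = to_stochastic(sub)
        ss = stable_state(p_sub, labels=sub.labels)
        p[np.ix_(idx, idx)] = p_sub
        pi_full[idx] = ss.pi
        closed = tuple(tuple(int(idx[i]) for i in cls) for cls in ss.closed_classes)
        weights = ss.class_weights
    return tcm, p, StableStateDistribution(
        labels=labels, pi=pi_full, closed_classes=closed, class_weights=weights
    )


@dataclass(frozen=True)
class MatrixComparison:
    transition_p: float
    state_p: float
    transition_g: GTestResult
    state_g: GTestResult
    low_power: bool


def compare_matrices(
    m1: TransitionCountMatrix, m2: TransitionCountMatrix
) -> MatrixComparison:
    """Homogeneity G-tests between two transition-count matrices.

    Transition structure: the two flattened count matrices stacked into a
    2 x k^2 table. State structure: the two row-marginal state-count vectors
    stacked into a 2 x k table. Matrices whose cells are all <= 2 are flagged
    low-power rather than rejected.
    """
    if m1.labels != m2.labels:
        raise MappingError("matrices must share the same state labels")
    flat = np.stack([m1.counts.ravel(), m2.counts.ravel()])
    states = np.stack([m1.counts.sum(axis=1), m2.counts.sum(axis=1)])
    gt = g_test(flat[:, flat.sum(axis=0) > 0])
    gs = g_test(states[:, states.sum(axis=0) > 0])
    low_power = bool(max(m1.counts.max(), m2.counts.max()) <= 2)
    return MatrixComparison(
        transition_p=gt.p, state_p=gs.p, transition_g=gt, state_g=gs, low_power=low_power
    )
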