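"""Assemblage series, G-test merging, transition tabulation, stable states."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import antbiogeo as ab
from antbiogeo.errors import EstimationError, FormatError, ParameterError
from antbiogeo.markov import (
    PlotSeries,
    TransitionCountMatrix,
    build_plot_series,
    compare_matrices,
    fill_gaps,
    four_state_projection,
    g_test,
    merge_indistinguishable,
    reduce_states,
    stable_state,
    tabulate_transitions,
    to_stochastic,
    trim_rare,
)
from antbiogeo.occurrence import EventTable

from conftest import make_event, make_table


def series_of(assemblages, plot_id="p", sampled=None):
    return PlotSeries(
        plot_id=plot_id,
        steps=tuple(range(len(assemblages))),
        assemblages=tuple(frozenset(a) for a in assemblages),
        sampled=tuple(sampled if sampled is not None else [True] * len(assemblages)),
    )


class TestBuildPlotSeries:
    def test_three_bins_make_three_steps(self):
        events = [
            make_event("e1", ["A"], week=18),
            make_event("e2", ["A", "B"], week=20),
            make_event("e3", ["B"], week=22),
        ]
        (series,) = build_plot_series(EventTable(events))
        assert len(series.steps) == 3
        assert series.assemblages == (
            frozenset({"A"}), frozenset({"A", "B"}), frozenset({"B"})
        )

    def test_events_in_one_bin_union(self):
        events = [
            make_event("e1", ["A"], week=18, method="pitfall"),
            make_event("e2", ["B"], week=19, method="malaise"),
        ]
        (series,) = build_plot_series(EventTable(events))
        assert series.assemblages == (frozenset({"A", "B"}),)

    def test_unsampled_middle_bin_is_empty_before_gap_fill(self):
        events = [make_event("e1", ["A"], week=18), make_event("e3", ["A"], week=26)]
        (series,) = build_plot_series(EventTable(events))
        assert series.sampled == (True, False, False, False, True)
        assert series.assemblages[1] == frozenset()

    def test_missing_site_id_is_a_format_error(self):
        with pytest.raises(FormatError):
            build_plot_series(EventTable([make_event("e1", ["A"], site="")]))


class TestFillGaps:
    def test_disappear_reappear_filled(self):
        s = fill_gaps(series_of([{"A"}, set(), {"A"}]))
        assert s.assemblages == (frozenset("A"),) * 3

    def test_rule_applies_per_species(self):
        s = fill_gaps(series_of([{"A"}, {"B"}, {"A"}]))
        assert s.assemblages == (
            frozenset({"A"}), frozenset({"A", "B"}), frozenset({"A"})
        )

    def test_idempotent_and_never_removes(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            raw = series_of(
                [
                    {sp for sp in "ABCD" if rng.random() < 0.4}
                    for _ in range(int(rng.integers(2, 8)))
                ]
            )
            once = fill_gaps(raw)
            assert fill_gaps(once).assemblages == once.assemblages
            for before, after in zip(raw.assemblages, once.assemblages):
                assert before <= after


class TestTrimRare:
    def test_coverage_prefix(self):
        counts = {"A": 50, "B": 30, "C": 15, "D": 4, "E": 1}
        sets = [[sp] for sp, n in counts.items() for _ in range(n)]
        assert trim_rare(make_table(sets), 0.95) == {"A", "B", "C"}

    def test_single_species_retained(self):
        assert trim_rare(make_table([["A"]])) == {"A"}

    def test_full_coverage_keeps_everything(self):
        table = make_table([["A"], ["B"], ["C"]])
        assert trim_rare(table, 1.0) == {"A", "B", "C"}

    def test_retained_share_meets_coverage_and_grows(self, small_park):
        events, _ = small_park
        occ = ab.aggregate_occurrences(events)
        totals = occ.data.sum(axis=1)
        prev = set()
        for cov in (0.5, 0.8, 0.95, 1.0):
            kept = trim_rare(events, cov)
            assert totals[list(kept)].sum() / totals.sum() >= cov
            assert prev <= kept
            prev = set(kept)


class TestGTest:
    def test_perfect_independence(self):
        r = g_test([[10, 10], [10, 10]])
        assert r.g == 0 and r.p == 1

    def test_formula_example(self):
        r = g_test([[20, 5], [5, 20]])
        expected = 2 * (2 * 20 * np.log(1.6) + 2 * 5 * np.log(0.4))
        assert r.g == pytest.approx(expected)
        assert r.g == pytest.approx(19.27, abs=0.01)
        assert r.df == 1

    def test_duplicated_rows_carry_no_signal(self):
        r = g_test([[7, 3, 5], [7, 3, 5]])
        assert r.g == pytest.approx(0, abs=1e-12)

    def test_matches_scipy_log_likelihood(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            table = rng.integers(1, 40, size=(3, 4))
            mine = g_test(table)
            g, p, df, _ = chi2_contingency(table, correction=False,
                                           lambda_="log-likelihood")
            assert mine.g == pytest.approx(g)
            assert mine.p == pytest.approx(p)
            assert mine.df == df

    def test_degenerate_table_rejected(self):
        with pytest.raises(EstimationError):
            g_test([[0, 0], [1, 2]])


class TestMergeIndistinguishable:
    def test_identical_profiles_merge_to_intersection(self):
        # AB and BC both always transition to the same sink assemblage, so
        # their target profiles are identical and they merge to {B}
        series = [
            series_of([{"A", "B"}, {"E"}] * 6, plot_id="p1"),
            series_of([{"B", "C"}, {"E"}] * 6, plot_id="p2"),
        ]
        classes = merge_indistinguishable(series, alpha=0.05)
        assert frozenset({"B"}) in classes.species_sets
        assert frozenset({"A", "B"}) not in classes.species_sets

    def test_maximally_distinguishable_profiles_stay_separate(self):
        # two self-persistent states that never interchange
        series = [
            series_of([{"A"}] * 60, plot_id="p1"),
            series_of([{"B"}] * 60, plot_id="p2"),
        ]
        classes = merge_indistinguishable(series, alpha=0.05)
        assert set(classes.species_sets) == {frozenset({"A"}), frozenset({"B"})}

    def test_three_mutually_indistinguishable_collapse_to_core(self):
        series = [
            series_of([{"A", "B"}, {"E"}] * 4, plot_id="p1"),
            series_of([{"B", "C"}, {"E"}] * 4, plot_id="p2"),
            series_of([{"B", "D"}, {"E"}] * 4, plot_id="p3"),
        ]
        classes = merge_indistinguishable(series, alpha=0.05)
        assert frozenset({"B"}) in classes.species_sets
        for original in ({"A", "B"}, {"B", "C"}, {"B", "D"}):
            assert frozenset(original) not in classes.species_sets

    def test_as_printed_rule_is_available(self):
        series = [
            series_of([{"A"}] * 60, plot_id="p1"),
            series_of([{"B"}] * 60, plot_id="p2"),
        ]
        classes = merge_indistinguishable(series, merge_rule="as_printed")
        # under the printed reading, *rejected* pairs merge instead
        assert classes.species_sets == (frozenset(),)


class TestTabulateTransitions:
    def test_self_transitions_on_diagonal(self):
        series = [series_of([{"A"}] * 5)]
        tcm = tabulate_transitions(series, [frozenset({"A"})])
        assert tcm.counts.tolist() == [[4]]

    def test_multi_counting_convention(self):
        """AB -> BC counts A->B, A->C, B->B, B->C with singleton states."""
        series = [series_of([{"A", "B"}, {"B", "C"}])]
        states = [frozenset({s}) for s in "ABC"]
        tcm = tabulate_transitions(series, states)
        expected = np.array([[0, 1, 1], [0, 1, 1], [0, 0, 0]])
        assert (tcm.counts == expected).all()

    def test_empty_series_zero_matrix(self):
        tcm = tabulate_transitions([], [frozenset({"A"})])
        assert tcm.n_transitions == 0

    def test_unsampled_gap_breaks_the_series(self):
        s = series_of([{"A"}, set(), {"B"}], sampled=[True, False, True])
        tcm = tabulate_transitions([s], [frozenset({"A"}), frozenset({"B"})])
        assert tcm.n_transitions == 0  # no transition across the unsampled gap


class TestReduceStates:
    @staticmethod
    def matrix(counts, labels):
        return TransitionCountMatrix(
            labels=tuple(labels),
            species_sets=tuple(frozenset(l) for l in labels),
            counts=np.asarray(counts),
        )

    def test_identical_columns_merge(self):
        m = self.matrix([[10, 5, 5], [4, 8, 8], [2, 3, 3]], ["A", "B", "AB"])
        red = reduce_states(m)
        assert len(red.labels) == 2
        assert red.counts.sum() == m.counts.sum()

    def test_distinguishable_columns_unchanged(self):
        m = self.matrix([[200, 5, 5], [5, 200, 5], [5, 5, 200]], ["A", "B", "C"])
        red = reduce_states(m, alpha=0.05)
        assert red.labels == m.labels
        assert (red.counts == m.counts).all()

    def test_near_duplicate_pair_reduces_to_two_states(self):
        m = self.matrix(
            [[120, 30, 29], [20, 80, 81], [18, 79, 84]], ["A", "B", "BC"]
        )
        red = reduce_states(m, alpha=0.05)
        assert len(red.labels) == 2
        assert frozenset({"B"}) in red.species_sets


class TestStableState:
    def test_single_state(self):
        pi = stable_state(np.array([[1.0]]))
        assert pi.pi.tolist() == [1.0]

    def test_analytic_two_state(self):
        pi = stable_state(np.array([[0.9, 0.1], [0.5, 0.5]]))
        assert pi.pi == pytest.approx([5 / 6, 1 / 6])

    def test_matches_power_iteration_on_random_matrices(self):
        """pi from the eigen solve equals brute-force power iteration to 1e-8."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = int(rng.integers(2, 9))
            p = rng.random((k, k)) + 1e-3
            p /= p.sum(axis=1, keepdims=True)
            pi = stable_state(p).pi
            v = np.full(k, 1 / k)
            for _ in range(10000):
                nxt = v @ p
                if np.abs(nxt - v).max() < 1e-14:
                    v = nxt
                    break
                v = nxt
            assert np.abs(pi - v).max() < 1e-8
            assert pi @ p == pytest.approx(pi, abs=1e-10)

    def test_reducible_chain_weights_closed_classes(self):
        # state 0 transient, states 1 and 2 absorbing
        p = np.array([[0.0, 0.5, 0.5], [0, 1, 0], [0, 0, 1]])
        pi = stable_state(p)
        assert pi.pi == pytest.approx([0.0, 0.5, 0.5])

    def test_non_stochastic_rejected(self):
        with pytest.raises(ParameterError):
            stable_state(np.array([[0.5, 0.2], [0.3, 0.7]]))


class TestFourStateProjection:
    def test_single_dominant_series_concentrates_pi(self):
        d1 = ab.markov.DEFAULT_DOMINANTS[0]
        series = [series_of([{d1}] * 10)]
        with pytest.warns(UserWarning):
            tcm, p, pi = four_state_projection(series)
        assert pi.pi[0] == pytest.approx(1.0)

    def test_no_dominants_all_mass_on_other(self):
        series = [series_of([{"x"}, {"y"}, {"x", "y"}] * 3)]
        with pytest.warns(UserWarning):
            tcm, p, pi = four_state_projection(series)
        assert pi.pi[-1] == pytest.approx(1.0)

    def test_known_chain_recovered(self):
        truth = np.array(
            [
                [0.80, 0.08, 0.06, 0.06],
                [0.10, 0.74, 0.08, 0.08],
                [0.05, 0.10, 0.75, 0.10],
                [0.08, 0.10, 0.12, 0.70],
            ]
        )
        states = tuple(
            [frozenset({d}) for d in ab.markov.DEFAULT_DOMINANTS] + [None]
        )
        events = ab.simulate_state_chain(truth, states, n_plots=2000, n_steps=6, seed=3)
        series = [fill_gaps(s) for s in build_plot_series(events)]
        tcm, p, pi = four_state_projection(series)
        assert np.abs(p - truth).max() < 0.05


class TestCompareMatrices:
    @staticmethod
    def matrix(counts):
        k = len(counts)
        return TransitionCountMatrix(
            labels=tuple(str(i) for i in range(k)),
            species_sets=tuple(frozenset({str(i)}) for i in range(k)),
            counts=np.asarray(counts),
        )

    def test_proportional_tables_indistinguishable(self):
        m1 = self.matrix([[10, 5], [4, 20]])
        m2 = self.matrix([[20, 10], [8, 40]])
        cmp = compare_matrices(m1, m2)
        assert cmp.transition_p == pytest.approx(1.0)
        assert cmp.state_p == pytest.approx(1.0)

    def test_different_chains_detected(self):
        m1 = self.matrix([[300, 20], [20, 300]])
        m2 = self.matrix([[100, 220], [230, 90]])
        cmp = compare_matrices(m1, m2)
        assert cmp.transition_p < 0.01

    def test_tiny_counts_flagged_low_power(self):
        m1 = self.matrix([[2, 1], [1, 2]])
        m2 = self.matrix([[1, 2], [2, 1]])
        cmp = compare_matrices(m1, m2)
        assert cmp.low_power

    def test_disturbance_shift_detected_in_most_replicates(self):
        """Dominant-favouring disturbance shifts the 4-state structure."""
        hits = 0
        reps = 50
        for seed in range(reps):
            base = dataclasses.replace(
                ab.default_config(), islands=(("X", 0.5, 0.5),),
                sites_per_island=6, events_per_island_week=6,
                years=(2005, 2006), seed=seed,
            )
            disturbed = dataclasses.replace(base, disturbance=0.6, seed=seed + 10_000)
            mats = []
            for cfg in (base, disturbed):
                events, _ = ab.simulate_park(cfg)
                series = [fill_gaps(s) for s in build_plot_series(events)]
                tcm, _, _ = four_state_projection(series)
                mats.append(tcm)
            cmp = compare_matrices(*mats)
            hits += cmp.transition_p < 0.05 or cmp.state_p < 0.05
        assert hits >= 0.8 * reps


def test_to_stochastic_zero_row_becomes_absorbing():
    m = TransitionCountMatrix(
        labels=("A", "B"),
        species_sets=(frozenset("A"), frozenset("B")),
        counts=np.array([[3, 1], [0, 0]]),
    )
    with pytest.warns(UserWarning):
        p = to_stochastic(m)
    assert p[1, 1] == 1.0
    assert p.sum(axis=1) == pytest.approx([1, 1])
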