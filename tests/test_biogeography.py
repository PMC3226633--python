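"""Island classification, geography regressions, and the fixed-factor ANCOVA."""

import numpy as np
import pandas as pd
import pytest

import antbiogeo as ab
from antbiogeo.biogeography import ancova, classify_island, regress_metric
from antbiogeo.errors import EstimationError, ParameterError
from antbiogeo.occurrence import IslandGeo


class TestClassifyIsland:
    def test_calf_is_far(self):
        c = classify_island(IslandGeo("Calf", 0.07, 3.29))
        assert c.distance_class == "far"

    def test_thompson_on_area_cutoff_is_large(self):
        """Half-open intervals: 0.54 km^2 sits in the large class."""
        c = classify_island(IslandGeo("Thompson", 0.54, 0.51))
        assert c.size_class == "large"

    def test_zero_isolation_is_near(self):
        c = classify_island(IslandGeo("Worlds End", 1.08, 0.0))
        assert c.distance_class == "near"

    def test_classification_is_pure(self, printed):
        once = [classify_island(g) for g in printed.geography]
        twice = [classify_island(g) for g in reversed(printed.geography)]
        assert sorted(map(repr, once)) == sorted(map(repr, twice))

    def test_printed_geography_split(self, printed):
        classes = [classify_island(g) for g in printed.geography]
        near = sum(c.distance_class == "near" for c in classes)
        large = sum(c.size_class == "large" for c in classes)
        # printed cutoffs yield 7 near / 3 far and 2 large / 8 small
        assert (near, large) == (7, 2)


class TestRegressMetric:
    def test_collinear_points_give_perfect_fit(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r = regress_metric(2 * x + 1, x)
        assert r.adj_r2 == pytest.approx(1.0)
        assert r.p_value < 1e-8
        assert r.slope == pytest.approx(2.0)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ParameterError):
            regress_metric([1, 2, 3], [5, 5, 5])

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            regress_metric([1, 2], [1, 2])

    def test_log_log_transform_requires_positive(self):
        with pytest.raises(ParameterError):
            regress_metric([1, 2, 3], [0.0, 1, 2], transform="log-log")

    def test_null_simulation_p_values_roughly_uniform(self):
        """Permuted labels: the slope test rejects at about its nominal rate."""
        rng = np.random.default_rng(99)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        hits = 0
        reps = 1000
        for _ in range(reps):
            hits += regress_metric(rng.permutation(y), x).p_value < 0.05
        assert 0.03 <= hits / reps <= 0.08

    def test_independent_metric_slope_centred_on_zero(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 12)
        slopes = [
            regress_metric(rng.normal(size=12), x).slope for _ in range(300)
        ]
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se + 0.05


def brute_force_sequential_ss(y, blocks):
    """Type-I sums of squares by nested projections (independent oracle)."""
    y = np.asarray(y, float)
    n = len(y)
    x = np.ones((n, 1))
    ss = []
    prev_fit = x @ np.linalg.lstsq(x, y, rcond=None)[0]
    for block in blocks:
        x = np.hstack([x, block])
        fit = x @ np.linalg.lstsq(x, y, rcond=None)[0]
        ss.append(float(np.sum((fit - prev_fit) ** 2)))
        prev_fit = fit
    sse = float(np.sum((y - prev_fit) ** 2))
    return ss, sse


def make_obs(cls, week, value):
    return pd.DataFrame({"island_class": cls, "week": week, "value": value})


class TestAncova:
    def test_pure_group_shift_matches_one_way_f(self):
        rng = np.random.default_rng(0)
        n = 12
        half = np.tile(np.arange(1, 5), 3)  # weeks within one group
        week = np.concatenate([half, half]).astype(float)
        cls = ["a"] * n + ["b"] * n
        y = rng.normal(size=2 * n)
        y[n:] += 2.5
        table = ancova(make_obs(cls, week, y))
        # one-way F from the pooled two-sample statistic
        a, b = y[:n], y[n:]
        ssb = n * ((a.mean() - y.mean()) ** 2 + (b.mean() - y.mean()) ** 2)
        # class F uses the full-model residual, so compare via the oracle below
        blocks = [
            (np.array(cls) == "b").astype(float)[:, None],
            week[:, None],
        ]
        blocks.append(blocks[0] * blocks[1])
        ss, sse = brute_force_sequential_ss(y, blocks)
        assert table.terms["sum_sq"].iloc[0] == pytest.approx(ss[0], rel=1e-8)
        assert ssb == pytest.approx(ss[0], rel=1e-6)

    def test_constant_response_gives_zero_f(self):
        table = ancova(make_obs(["a", "a", "b", "b"] * 3, list(range(12)), [5.0] * 12))
        assert (table.terms["F"] == 0).all()
        assert (table.terms["p"] == 1).all()

    def test_week_effect_only(self):
        week = np.array(list(range(1, 7)) * 2, dtype=float)
        cls = ["a"] * 6 + ["b"] * 6
        table = ancova(make_obs(cls, week, week.copy()))
        assert table.terms.loc["week", "sum_sq"] > 0
        assert table.terms.loc["class", "F"] == pytest.approx(0, abs=1e-8)

    def test_f_matches_projection_oracle_on_random_designs(self):
        """Sequential-SS ANCOVA must agree with nested projections to 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(12, 31))
            # each class needs >= 2 distinct weeks or the interaction aliases
            cls = np.concatenate([["a", "a", "b", "b"], rng.choice(["a", "b"], size=n - 4)])
            week = np.concatenate(
                [[18.0, 25.0, 19.0, 27.0], rng.integers(18, 30, size=n - 4).astype(float)]
            )
            y = rng.normal(size=n)
            ind = (cls == "b").astype(float)[:, None]
            blocks = [ind, week[:, None], ind * week[:, None]]
            ss, sse = brute_force_sequential_ss(y, blocks)
            table = ancova(make_obs(cls, week, y))
            for got, want in zip(table.terms["sum_sq"], ss):
                assert got == pytest.approx(want, rel=1e-8, abs=1e-8)
            assert table.residual_ss == pytest.approx(sse, rel=1e-8)
            dfs = list(table.terms["df"]) + [table.residual_df]
            assert sum(dfs) == n - 1

    def test_single_class_is_an_aliasing_error(self):
        with pytest.raises(EstimationError, match="class"):
            ancova(make_obs(["a"] * 6, list(range(6)), list(range(6))))


def test_synthetic_park_recovers_biogeographic_signs():
    """Estimated island S rises with area and falls with isolation."""
    import dataclasses

    ok = 0
    reps = 12
    for seed in range(reps):
        cfg = dataclasses.replace(ab.default_config(), years=(2005, 2006), seed=seed)
        events, truth = ab.simulate_park(cfg)
        rows = []
        for name, area, iso in cfg.islands:
            sub = events.by_island()[name]
            est = ab.active_species(sub, "year", n_iterations=10, seed=seed)["year"]
            rows.append((est.s_mean, area, iso))
        s, area, iso = map(np.array, zip(*rows))
        if regress_metric(s, area).slope > 0 and regress_metric(s, iso).slope < 0:
            ok += 1
    assert ok >= 0.8 * reps
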