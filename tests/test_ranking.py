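import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligoscore.ranking import (
    ScoreTable, bootstrap_h2h, classify_difficulty, first_pick_rate,
    impute_missing, phase_delta, quantile95, rank_groups, two_round_z,
)


def table_from(rows):
    return ScoreTable(pd.DataFrame(rows, columns=[
        "group", "target", "phase", "model", "metric", "value"]))


class TestImputeMissing:
    def test_missing_filled_with_target_minimum(self):
        t = table_from([
            ("g1", "T1", "1", 1, "ics", 0.7),
            ("g2", "T1", "1", 1, "ics", 0.4),
            ("g3", "T1", "1", 1, "ics", np.nan),
        ])
        out = impute_missing(t).df
        assert out.loc[2, "value"] == pytest.approx(0.4)
        assert out.loc[2, "imputed"]

    def test_complete_table_unchanged(self):
        t = table_from([("g1", "T1", "1", 1, "ics", 0.7),
                        ("g2", "T1", "1", 1, "ics", 0.4)])
        out = impute_missing(t).df
        assert out["value"].tolist() == [0.7, 0.4]
        assert not out["imputed"].any()

    def test_all_missing_warns_and_stays_missing(self):
        t = table_from([("g1", "T1", "1", 1, "ics", np.nan),
                        ("g2", "T1", "1", 1, "ics", np.nan)])
        with pytest.warns(UserWarning):
            out = impute_missing(t).df
        assert out["value"].isna().all()


class TestTwoRoundZ:
    def test_constant_values_give_zero(self):
        assert np.allclose(two_round_z([0.5] * 6), 0.0)

    def test_single_outlier_excluded_then_floored(self):
        z = two_round_z([1, 1, 1, 1, -100])
        assert np.allclose(z[:4], 0.0)
        assert z[4] == -2.0

    def test_two_values_population_sd(self):
        assert np.allclose(two_round_z([2, 0]), [1.0, -1.0])

    def test_short_input_gives_zeros(self):
        assert np.allclose(two_round_z([0.3]), 0.0)

    @given(st.lists(st.integers(-1000, 1000), min_size=2, max_size=20),
           st.floats(0.1, 50), st.floats(-100, 100))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_affine_invariance(self, values, a, b):
        # integer-derived values keep the spread well above float round-off
        x = np.asarray(values, dtype=float) / 10.0
        assert np.allclose(two_round_z(a * x + b), two_round_z(x),
                           atol=1e-6, rtol=1e-6)

    def test_kept_set_z_sums_to_zero(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            x = rng.normal(size=rng.integers(3, 30))
            z = two_round_z(x)
            kept = z[z > -2.0]
            if len(kept) and z.min() > -2.0 + 1e-9:
                assert abs(kept.sum()) < 1e-9


def planted_table(n_targets=8, groups=("good", "mid", "bad"), seed=0):
    rng = np.random.default_rng(seed)
    base = {"good": 0.9, "mid": 0.6, "bad": 0.3}
    rows = []
    for t in range(n_targets):
        for g in groups:
            for m in range(1, 6):
                for metric in ("ics", "dockq"):
                    v = np.clip(base[g] + rng.normal(0, 0.05), 0, 1)
                    rows.append((g, f"T{t}", "1", m, metric, v))
    return table_from(rows)


class TestRankGroups:
    def test_single_group_single_target(self):
        t = table_from([("g1", "T1", "1", m, "ics", v)
                        for m, v in [(1, 0.5), (2, 0.8), (3, 0.2)]])
        res = rank_groups(t, "best")
        expected = two_round_z([0.5, 0.8, 0.2]).max()
        assert res.cumulative["g1"] == pytest.approx(expected)

    def test_planted_dominance_recovered(self):
        res = rank_groups(planted_table(), "best")
        assert res.ordering == ["good", "mid", "bad"]

    def test_best_never_below_first(self):
        for seed in range(5):
            t = planted_table(seed=seed)
            best = rank_groups(t, "best").cumulative
            first = rank_groups(t, "first").cumulative
            for g in best.index:
                assert best[g] >= first[g] - 1e-12

    def test_model6_excluded_from_selection(self):
        t = table_from([("g1", "T1", "1", 1, "ics", 0.2),
                        ("g1", "T1", "1", 6, "ics", 0.9),
                        ("g2", "T1", "1", 1, "ics", 0.5)])
        res = rank_groups(t, "best")
        # model 6 may not be selected; g1's z comes from model 1
        assert res.per_target.query("group == 'g1'")["model"].tolist() == [1]


class TestBootstrapH2H:
    def test_dominance_gives_one(self):
        t = planted_table()
        assert bootstrap_h2h(t, "good", "bad", n=200, seed=3) == 1.0

    def test_identical_groups_give_zero_under_strict_inequality(self):
        rows = []
        for tgt in range(4):
            for g in ("a", "b"):
                for m in (1, 2):
                    rows.append((g, f"T{tgt}", "1", m, "ics", 0.1 * tgt + 0.05 * m))
        t = table_from(rows)
        assert bootstrap_h2h(t, "a", "b", n=100, seed=1) == 0.0

    def test_seed_reproducibility(self):
        t = planted_table(n_targets=5, seed=4)
        f1 = bootstrap_h2h(t, "good", "mid", n=300, seed=42)
        f2 = bootstrap_h2h(t, "good", "mid", n=300, seed=42)
        assert f1 == f2

    def test_no_common_targets_raises(self):
        t = table_from([("a", "T1", "1", 1, "ics", 0.5),
                        ("b", "T2", "1", 1, "ics", 0.5)])
        with pytest.raises(ValueError):
            bootstrap_h2h(t, "a", "b", n=10, seed=0)


class TestFirstPickRate:
    def test_counts_targets_where_first_is_best(self):
        rows = []
        # 3 of 5 targets have the best model first
        for tgt, first_best in enumerate([True, True, True, False, False]):
            vals = [0.9, 0.5, 0.4] if first_best else [0.4, 0.9, 0.5]
            for m, v in enumerate(vals, start=1):
                rows.append(("g", f"T{tgt}", "1", m, "ics", v))
            rows.append(("other", f"T{tgt}", "1", 1, "ics", 0.3))
        assert first_pick_rate(table_from(rows), "g") == pytest.approx(0.6)

    def test_single_model_target_counts_as_success(self):
        t = table_from([("g", "T1", "1", 1, "ics", 0.4),
                        ("other", "T1", "1", 1, "ics", 0.9)])
        assert first_pick_rate(t, "g") == 1.0


class TestDifficulty:
    @pytest.mark.parametrize("dockq95, tm95, expected", [
        (0.03, 0.95, "difficult"),   # low interface accuracy
        (0.95, 0.99, "easy"),
        (0.45, 0.79, "difficult"),   # TM-score branch
        (0.4, 0.8, "easy"),          # boundary: rule is strict <
    ])
    def test_rule(self, dockq95, tm95, expected):
        assert classify_difficulty(dockq95, tm95) == expected

    def test_missing_input_gives_missing_label(self):
        assert classify_difficulty(None, 0.9) is None
        assert classify_difficulty(np.nan, 0.9) is None


class TestQuantile95:
    def test_constant_values(self):
        assert quantile95([0.7] * 20) == pytest.approx(0.7)

    def test_linear_interpolation(self):
        assert quantile95(range(20)) == pytest.approx(18.05)

    def test_single_value(self):
        assert quantile95([0.31]) == pytest.approx(0.31)

    def test_empty_is_missing(self):
        assert quantile95([]) is None


class TestPhaseDelta:
    def rows(self, deltas):
        rows = []
        for t, d in enumerate(deltas):
            rows.append(("g", f"T{t}", "0", 1, "dockq", 0.5))
            rows.append(("g", f"T{t}", "1", 1, "dockq", 0.5 + d))
        return table_from(rows)

    def test_identical_phases_give_zero(self):
        assert phase_delta(self.rows([0, 0]), "g") == pytest.approx(0.0)

    def test_mean_of_per_target_deltas(self):
        assert phase_delta(self.rows([0.1, 0.2]), "g") == pytest.approx(0.15)

    def test_no_shared_targets_is_missing(self):
        t = table_from([("g", "T1", "0", 1, "dockq", 0.5),
                        ("g", "T2", "1", 1, "dockq", 0.6)])
        assert phase_delta(t, "g") is None

    def test_uses_first_models_only(self):
        t = table_from([
            ("g", "T1", "0", 1, "dockq", 0.2),
            ("g", "T1", "0", 2, "dockq", 0.9),
            ("g", "T1", "1", 1, "dockq", 0.5),
        ])
        assert phase_delta(t, "g") == pytest.approx(0.3)
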