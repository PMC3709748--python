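"""Differential-expression module: the moderated d statistic, the
exchangeability constant, permutation FDR, fold changes and selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirpin.diffexpr import (
    SamConfig,
    choose_s0,
    de_table,
    evaluate_cv,
    fold_changes,
    permutation_q_values,
    sam_d_statistics,
    select_differential,
)
from mirpin.io import UsageError
from mirpin.simulate import simulate_expression

from conftest import make_matrix


class TestDStatistic:
    def test_pooled_scatter_hand_computation(self, toy_matrix):
        matrix, labels = toy_matrix
        stats = sam_d_statistics(matrix, labels, s0=0.0)
        assert stats.loc["f0", "s"] == pytest.approx(0.70711, abs=1e-5)
        assert stats.loc["f0", "d"] == pytest.approx(4.24264, abs=1e-5)

    def test_zero_when_groups_identical(self):
        matrix, labels = make_matrix([[3.0, 4.0, 3.0, 4.0]])
        assert sam_d_statistics(matrix, labels, 0.0).loc["f0", "d"] == 0.0

    def test_location_invariance(self, rng):
        base = rng.normal(5, 1, size=(20, 8))
        m1, labels = make_matrix(base)
        m2, _ = make_matrix(base + 7.25)
        d1 = sam_d_statistics(m1, labels, 0.1)["d"]
        d2 = sam_d_statistics(m2, labels, 0.1)["d"]
        assert np.allclose(d1, d2)

    def test_antisymmetric_under_group_swap(self, rng):
        base = rng.normal(5, 1, size=(10, 6))
        matrix, labels = make_matrix(base, n_normal=3)
        swapped = {s: ("tumor" if g == "normal" else "normal")
                   for s, g in labels.mapping.items()}
        from mirpin.io import GroupLabels
        d1 = sam_d_statistics(matrix, labels, 0.1)["d"]
        d2 = sam_d_statistics(matrix, GroupLabels(swapped), 0.1)["d"]
        assert np.allclose(d1, -d2)

    def test_feature_with_single_observation_flagged(self):
        arr = np.array([[1.0, np.nan, 4.0, 5.0], [1.0, 2.0, 4.0, 5.0]])
        matrix, labels = make_matrix(arr)
        stats = sam_d_statistics(matrix, labels, 0.0)
        assert math.isnan(stats.loc["f0", "d"])
        assert math.isfinite(stats.loc["f1", "d"])


class TestChooseS0:
    def test_median_strategy(self):
        assert choose_s0([1.0, 2.0, 3.0], "median_s") == 2.0

    def test_all_zero_scatter(self):
        assert choose_s0([0.0, 0.0], "percentile_search", numerators=[1.0, 1.0]) == 0.0

    def test_constant_scatter_returns_smallest_candidate(self):
        s = np.full(50, 2.0)
        r = np.linspace(-1, 1, 50)
        assert choose_s0(s, "percentile_search", numerators=r) == 0.0

    def test_search_never_worse_than_zero(self, rng):
        # 1000 features with scatter-dependent spread; the selected s0 must
        # give a coefficient of variation no larger than s0 = 0
        s = rng.uniform(0.05, 2.0, size=1000)
        r = rng.normal(0, 1, size=1000) * s
        s0 = choose_s0(s, "percentile_search", numerators=r)
        assert evaluate_cv(s, r, s0) <= evaluate_cv(s, r, 0.0) + 1e-12


class TestPermutationQ:
    def _planted_case(self, rng, n_null=50, delta=6.0, sd=0.1):
        base = rng.uniform(4, 10, size=(n_null + 1, 1))
        arr = base + rng.normal(0, sd, size=(n_null + 1, 8))
        arr[0, 4:] += delta
        return make_matrix(arr)

    def test_planted_feature_gets_zero_q_under_full_enumeration(self, rng):
        matrix, labels = self._planted_case(rng)
        config = SamConfig(n_permutations=100, seed=1)  # C(8,4)=70 -> exhaustive
        q = permutation_q_values(matrix, labels, config)
        assert q.loc["f0"] == 0.0

    def test_exhaustive_q_matches_independent_enumeration(self, rng):
        """Recompute the planted-case q by explicit loops over all C(8,4)
        label assignments, independent of the vectorized implementation."""
        matrix, labels = self._planted_case(rng, n_null=15)
        config = SamConfig(n_permutations=100, seed=1, s0_strategy="median_s")
        q = permutation_q_values(matrix, labels, config)

        X = matrix.values.to_numpy()

        def d_stats(tumor_idx, s0):
            out = []
            for row in X:
                t = row[list(tumor_idx)]
                n = np.delete(row, list(tumor_idx))
                ss = ((t - t.mean()) ** 2).sum() + ((n - n.mean()) ** 2).sum()
                s = math.sqrt((1 / 4 + 1 / 4) * ss / 6)
                out.append(((t.mean() - n.mean()) / (s + s0), s))
            return out

        obs0 = d_stats(range(4, 8), 0.0)
        s0 = float(np.median([s for _, s in obs0]))
        d_obs = np.array([d for d, _ in d_stats(range(4, 8), s0)])
        perms = list(itertools.combinations(range(8), 4))
        null_abs = np.array([[abs(d) for d, _ in d_stats(p, s0)] for p in perms])
        expected = {}
        for i, t in enumerate(np.abs(d_obs)):
            counts = (null_abs >= t).sum(axis=1)
            obs_count = (np.abs(d_obs) >= t).sum()
            expected[i] = min(np.median(counts) / obs_count, 1.0)
        # monotonize independently
        order = np.argsort(-np.abs(d_obs))
        running = -np.inf
        mono = {}
        for idx in order:
            running = max(running, expected[idx])
            mono[idx] = running
        for i, fid in enumerate(matrix.feature_ids):
            assert q.loc[fid] == pytest.approx(mono[i], abs=1e-12)

    def test_range_and_monotonicity_on_noise(self, rng):
        matrix, labels = make_matrix(rng.normal(6, 1, size=(60, 10)))
        config = SamConfig(n_permutations=200, seed=3)
        table = de_table(matrix, labels, config)  # d and q share one s0
        assert table["q"].between(0, 1).all()
        ordered = table.sort_values("d", key=abs, ascending=False)["q"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()

    def test_invariant_under_sample_reordering(self, rng):
        matrix, labels = make_matrix(rng.normal(6, 1, size=(30, 8)))
        config = SamConfig(n_permutations=100, seed=5)
        q1 = permutation_q_values(matrix, labels, config)
        shuffled = matrix.values[list(np.array(matrix.sample_ids)[::-1])]
        from mirpin.io import ExpressionMatrix
        m2 = ExpressionMatrix(shuffled, scale_hint="log2")
        q2 = permutation_q_values(m2, labels, config)
        assert np.allclose(q1, q2)

    def test_exhaustive_mode_is_reproducible(self, rng):
        matrix, labels = self._planted_case(rng, n_null=10)
        config = SamConfig(n_permutations=100, seed=9)
        q1 = permutation_q_values(matrix, labels, config)
        q2 = permutation_q_values(matrix, labels, config)
        assert (q1 == q2).all()

    def test_degenerate_labels_rejected(self, rng):
        matrix, labels = make_matrix(rng.normal(6, 1, size=(5, 4)))
        from mirpin.io import GroupLabels
        all_tumor = GroupLabels({s: "tumor" for s in matrix.sample_ids})
        with pytest.raises(UsageError):
            permutation_q_values(matrix, all_tumor, SamConfig())


class TestFoldChange:
    def test_linear_ratio(self):
        matrix, labels = make_matrix([[2.0, 2.0, 1.0, 1.0]], scale_hint="linear")
        assert fold_changes(matrix, labels).loc["f0"] == pytest.approx(0.5)

    def test_reciprocal_under_group_swap(self, rng):
        from mirpin.io import GroupLabels
        matrix, labels = make_matrix(rng.lognormal(2, 0.5, size=(12, 6)),
                                     scale_hint="linear")
        swapped = GroupLabels({s: ("tumor" if g == "normal" else "normal")
                               for s, g in labels.mapping.items()})
        prod = fold_changes(matrix, labels) * fold_changes(matrix, swapped)
        assert np.allclose(prod, 1.0)

    def test_log2_input_exponentiated(self):
        matrix, labels = make_matrix([[1.0, 1.0, 3.0, 3.0]], scale_hint="log2")
        assert fold_changes(matrix, labels).loc["f0"] == pytest.approx(4.0)


class TestSelection:
    def _frame(self, q, fc):
        return pd.DataFrame({"feature_id": [f"f{i}" for i in range(len(q))],
                             "q": q, "fc": fc})

    def test_down_regulated_ratio_meets_threshold(self):
        # fc 0.38 => 1/0.38 = 2.63 >= 2.5: selected, down
        up, down = select_differential(self._frame([0.0], [0.38]),
                                       SamConfig(fc_threshold=2.5))
        assert up == set() and down == {"f0"}

    def test_unit_fold_change_never_selected(self):
        up, down = select_differential(self._frame([0.0], [1.0]),
                                       SamConfig(fc_threshold=1.0))
        assert up == down == set()

    def test_partition_is_disjoint(self, rng):
        frame = self._frame(rng.uniform(0, 1e-6, 50), rng.lognormal(0, 2, 50))
        up, down = select_differential(frame, SamConfig(fc_threshold=1.5))
        assert not up & down

    def test_recovery_on_planted_simulations(self):
        """Planted log2 effect 3, noise 0.5, 10v10, 5% planted: selection must
        recover >=95% of planted features with zero false positives."""
        hits = planted = fps = 0
        for seed in range(20):
            matrix, labels, truth = simulate_expression(
                200, 10, 10, de_fraction=0.05, log2_effect=3.0,
                noise_sd=0.5, seed=seed)
            config = SamConfig(n_permutations=500, seed=seed)
            table = de_table(matrix, labels, config)
            up, down = select_differential(table, config)
            truth_set = set(truth.planted_up_mirnas) | set(truth.planted_down_mirnas)
            planted += len(truth_set)
            hits += len((up | down) & truth_set)
            fps += len((up | down) - truth_set)
        assert hits / planted >= 0.95
        assert fps == 0


def test_de_table_direction_calls_match_selection(rng):
    matrix, labels, truth = simulate_expression(
        60, 6, 6, de_fraction=0.2, log2_effect=4.0, noise_sd=0.3, seed=11)
    table = de_table(matrix, labels, SamConfig(n_permutations=300, seed=11))
    up, down = select_differential(table, SamConfig(n_permutations=300, seed=11))
    assert set(table.loc[table["direction"] == "up", "feature_id"]) == up
    assert set(table.loc[table["direction"] == "down", "feature_id"]) == down
    assert ((table["direction"] == "down") <= (table["fc"] < 1)).all()
    assert ((table["direction"] == "up") <= (table["fc"] > 1)).all()
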