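"""Unit and property tests for the five gene-set scorers and the consensus."""

import numpy as np
import pandas as pd
import pytest

from oxistate.containers import GeneSet
from oxistate.scoring import (
    METHODS,
    assign_states,
    combine_scores,
    score_auc_recovery,
    score_binned_control,
    score_cells,
    score_rank_u,
    score_sample_rank,
    score_weighted_ks,
)

from oracles import (
    oracle_auc_recovery,
    oracle_binned_control,
    oracle_quartile_counts,
    oracle_rank_u,
    oracle_sample_rank,
    oracle_weighted_ks,
)


def _frame(rows, genes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"c{i}" for i in range(rows.shape[0])],
                        columns=genes)


class TestAucRecovery:
    def test_saturated_when_set_fills_top_ranks(self):
        # 3-gene set occupying ranks 1..3 with T=5 -> maximal recovery
        df = _frame([np.r_[[10, 9, 8], np.zeros(97)]])
        s = GeneSet("s", ("g0", "g1", "g2"))
        assert score_auc_recovery(df, s, top_frac=0.05).iloc[0] == 1.0

    def test_zero_when_no_set_gene_in_top_window(self):
        vals = np.r_[np.arange(100, 0, -1)].astype(float)
        df = _frame([vals])
        s = GeneSet("s", ("g99",))  # lowest-expressed gene
        assert score_auc_recovery(df, s, top_frac=0.05).iloc[0] == 0.0

    def test_hand_enumerated_curve(self):
        # 100 genes, T=5, set at ranks 2 and 4: sum y = 6, max = 9
        vals = np.arange(100, 0, -1).astype(float)
        df = _frame([vals])
        s = GeneSet("s", ("g1", "g3"))
        assert score_auc_recovery(df, s, top_frac=0.05).iloc[0] == pytest.approx(
            6 / 9
        )

    def test_matches_bruteforce_oracle(self, random_panels):
        panels, s = random_panels
        for df in panels:
            mask = df.columns.isin(s.members)
            got = score_auc_recovery(df, s)
            for i in range(0, 50, 10):
                exp = oracle_auc_recovery(df.iloc[i].to_numpy(), mask)
                assert abs(got.iloc[i] - exp) < 1e-9


class TestRankU:
    def test_perfect_front_ranks(self):
        df = _frame([np.r_[[9.0, 8.0], np.zeros(98)]])
        s = GeneSet("s", ("g0", "g1"))
        assert score_rank_u(df, s, r_max=50).iloc[0] == 1.0

    def test_single_gene_below_rmax_scores_zero(self):
        vals = np.arange(100, 0, -1).astype(float)
        df = _frame([vals])
        s = GeneSet("s", ("g99",))
        assert score_rank_u(df, s, r_max=50).iloc[0] == 0.0

    def test_invalid_rmax(self):
        df = _frame([np.arange(10.0)])
        with pytest.raises(ValueError):
            score_rank_u(df, GeneSet("s", ("g0",)), r_max=0)

    def test_matches_bruteforce_oracle(self, random_panels):
        panels, s = random_panels
        for df in panels:
            mask = df.columns.isin(s.members)
            got = score_rank_u(df, s, r_max=150)
            for i in range(0, 50, 10):
                exp = oracle_rank_u(df.iloc[i].to_numpy(), mask, r_max=150)
                assert abs(got.iloc[i] - exp) < 1e-9


class TestSampleRank:
    def test_extremes(self):
        vals = np.arange(1.0, 101.0)
        df = _frame([vals])
        top = GeneSet("top", ("g97", "g98", "g99"))
        bottom = GeneSet("bot", ("g0", "g1", "g2"))
        assert score_sample_rank(df, top).iloc[0] == pytest.approx(1.0)
        assert score_sample_rank(df, bottom).iloc[0] == pytest.approx(0.0)

    def test_degenerate_whole_matrix_set(self):
        df = _frame([np.arange(5.0)])
        with pytest.raises(ValueError, match="degenerate"):
            score_sample_rank(df, GeneSet("s", tuple(df.columns)))

    def test_matches_bruteforce_oracle(self, random_panels):
        panels, s = random_panels
        for df in panels:
            mask = df.columns.isin(s.members)
            got = score_sample_rank(df, s)
            for i in range(0, 50, 10):
                exp = oracle_sample_rank(df.iloc[i].to_numpy(), mask)
                assert abs(got.iloc[i] - exp) < 1e-9


class TestWeightedKS:
    def test_two_gene_hand_enumeration(self):
        df = _frame([[5.0, 1.0]])
        assert score_weighted_ks(df, GeneSet("s", ("g0",))).iloc[0] == pytest.approx(
            0.5
        )
        assert score_weighted_ks(df, GeneSet("s", ("g1",))).iloc[0] == pytest.approx(
            -0.5
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 60))
        df = _frame(vals)
        s = GeneSet("s", tuple(df.columns[:10]))
        base = score_weighted_ks(df, s)
        trans = score_weighted_ks(_frame(np.exp(3 * vals)), s)
        assert np.allclose(base, trans)

    def test_matches_bruteforce_oracle(self, random_panels):
        panels, s = random_panels
        for df in panels:
            mask = df.columns.isin(s.members)
            got = score_weighted_ks(df, s)
            for i in range(0, 50, 10):
                exp = oracle_weighted_ks(df.iloc[i].to_numpy(), mask)
                assert abs(got.iloc[i] - exp) < 1e-9


class TestBinnedControl:
    def test_flat_matrix_scores_zero(self):
        df = _frame(np.ones((4, 50)))
        s = GeneSet("s", tuple(df.columns[:5]))
        got = score_binned_control(df, s, n_bins=5, seed=0)
        assert np.allclose(got, 0.0)

    def test_seed_determinism(self, random_panels):
        panels, s = random_panels
        df = panels[0]
        a = score_binned_control(df, s, seed=7)
        b = score_binned_control(df, s, seed=7)
        c = score_binned_control(df, s, seed=8)
        assert np.array_equal(a.to_numpy(), b.to_numpy())
        assert not np.array_equal(a.to_numpy(), c.to_numpy())

    def test_matches_seeded_oracle(self, random_panels):
        panels, s = random_panels
        for df in panels[:5]:
            mask = np.asarray(df.columns.isin(s.members))
            got = score_binned_control(df, s, n_bins=1, n_ctrl=200, seed=3)
            exp = oracle_binned_control(df.to_numpy(), mask, 1, 200, 3)
            assert np.max(np.abs(got.to_numpy() - exp)) < 1e-9


class TestRankScorersMonotoneInvariance:
    """All rank-based scorers ignore strictly monotone per-cell transforms."""

    @pytest.mark.parametrize(
        "scorer",
        [score_auc_recovery, score_rank_u, score_sample_rank, score_weighted_ks],
    )
    def test_invariance(self, scorer, random_panels):
        panels, s = random_panels
        df = panels[0]
        base = scorer(df, s)
        trans = scorer(df * 7.0 + 1.0, s)  # strictly increasing, tie-preserving
        assert np.allclose(base.to_numpy(), trans.to_numpy())

    def test_scores_bounded(self, random_panels):
        panels, s = random_panels
        for df in panels[:5]:
            assert score_auc_recovery(df, s).between(0, 1).all()
            assert score_rank_u(df, s).between(0, 1).all()
            assert score_sample_rank(df, s).between(0, 1).all()
            assert score_weighted_ks(df, s).between(-1, 1).all()


class TestCombineScores:
    def test_hand_computed_three_cell_example(self):
        raw = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [3.0, 1.0, 2.0]})
        znorm, unit, composite = combine_scores(raw)
        assert np.allclose(unit["A"], [0.0, 0.5, 1.0])
        assert np.allclose(unit["B"], [1.0, 0.0, 0.5])
        assert np.allclose(composite, [1.0, 0.5, 1.5])

    def test_single_method_composite_is_minmax(self):
        raw = pd.DataFrame({"A": [5.0, 9.0, 7.0]})
        _, unit, composite = combine_scores(raw)
        assert composite.min() == 0.0 and composite.max() == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(rng.normal(size=(30, 5)), columns=list(METHODS))
        _, _, base = combine_scores(raw)
        shifted = raw.copy()
        shifted["rank_u"] = 10.0 * shifted["rank_u"] + 7.0
        _, _, moved = combine_scores(shifted)
        assert np.allclose(base, moved)

    def test_constant_column_contributes_zero_with_warning(self):
        raw = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            _, unit, composite = combine_scores(raw)
        assert np.allclose(unit["B"], 0.0)
        assert np.allclose(composite, unit["A"])

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            combine_scores(pd.DataFrame({"A": [1.0]}))


class TestAssignStates:
    def test_interpolated_quartiles_small_example(self):
        state, q1, q3 = assign_states(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert q1 == 1.75 and q3 == 3.25
        assert list(state) == ["low", "transition", "transition", "high"]

    def test_all_equal_scores_are_transition(self):
        state, _, _ = assign_states(pd.Series([2.0] * 10))
        assert (state == "transition").all()

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            assign_states(pd.Series([1.0, 2.0, 3.0]))

    def test_counts_match_sorting_oracle_on_distinct_scores(self):
        rng = np.random.default_rng(5)
        for n in (101, 1000, 4321):
            v = rng.permutation(n).astype(float)
            state, _, _ = assign_states(pd.Series(v))
            lo, hi = oracle_quartile_counts(v)
            assert (state == "low").sum() == lo
            assert (state == "high").sum() == hi


class TestPlantedSignal:
    def test_composite_separates_planted_active_cells(self, study, os_set):
        cells, truth = study
        panel = score_cells(cells, os_set, seed=0)
        active = truth.active_cells.loc[cells.cell_ids].to_numpy()
        assert panel.composite[active].mean() > panel.composite[~active].mean()

    def test_each_method_ranks_active_cells_higher(self, study, os_set):
        cells, truth = study
        panel = score_cells(cells, os_set, seed=0)
        active = truth.active_cells.loc[cells.cell_ids].to_numpy()
        for method in METHODS:
            col = panel.raw[method]
            assert col[active].mean() > col[~active].mean(), method
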