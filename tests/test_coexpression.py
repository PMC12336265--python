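"""Metacell construction, soft-power selection and module detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oxistate.containers import CellExpression
from oxistate.coexpression import (
    build_metacells,
    detect_modules,
    module_eigengenes,
    module_state_summary,
    scale_free_fit,
    scan_soft_powers_from_correlation,
    topological_overlap,
)
from oxistate.preprocess import log_normalize, qc_filter
from oxistate.simulate import SimConfig, simulate_cells


def _cells_from_normalized(values, sample="s1", counts=None):
    values = np.asarray(values, dtype=float)
    cells = pd.Index([f"c{i}" for i in range(values.shape[0])], name="cell")
    genes = [f"g{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame({"sample": sample, "condition": "control"}, index=cells)
    if counts is None:
        counts = np.rint(values * 10).astype(int)
    return CellExpression(
        counts=pd.DataFrame(counts, index=cells, columns=genes),
        cell_meta=meta,
        normalized=pd.DataFrame(values, index=cells, columns=genes),
    )


class TestBuildMetacells:
    def test_low_prevalence_gene_excluded(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2.0, 1.0, size=(100, 30))
        counts = np.rint(vals * 10).astype(int)
        counts[:, 0] = 0
        counts[:96, 1] = 0  # detected in 4% of cells -> excluded
        x = _cells_from_normalized(vals, counts=counts)
        mc = build_metacells(x, k=5, max_shared=2, groups=x.cell_meta["sample"])
        assert "g0" not in mc.expr.columns
        assert "g1" not in mc.expr.columns
        assert "g2" in mc.expr.columns

    def test_k1_metacells_equal_cells(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2.0, 1.0, size=(20, 15))
        x = _cells_from_normalized(vals)
        mc = build_metacells(x, k=1, max_shared=0, groups=x.cell_meta["sample"])
        assert mc.n_metacells == 20
        assert np.allclose(np.sort(mc.expr.to_numpy(), axis=0),
                           np.sort(x.normalized.to_numpy(), axis=0))

    def test_hand_computed_neighbor_means(self):
        # 4 cells on a line; with k=2 each metacell averages adjacent cells
        base = np.array([[0.0], [1.0], [10.0], [11.0]])
        vals = np.hstack([base, base, 5 + base])  # 3 informative genes
        x = _cells_from_normalized(vals)
        mc = build_metacells(
            x, k=2, max_shared=0, groups=x.cell_meta["sample"], n_pcs=1
        )
        profiles = {tuple(np.round(r, 6)) for r in mc.expr.to_numpy()}
        assert (0.5, 0.5, 5.5) in profiles  # mean of cells c0,c1
        assert (10.5, 10.5, 15.5) in profiles  # mean of cells c2,c3

    def test_small_group_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2.0, 1.0, size=(30, 10))
        x = _cells_from_normalized(vals)
        groups = pd.Series(
            ["big"] * 28 + ["tiny"] * 2, index=x.cell_ids
        )
        with pytest.warns(UserWarning, match="tiny"):
            mc = build_metacells(x, k=5, max_shared=2, groups=groups)
        assert all(g == "big" for g in mc.group_of.values())

    def test_gene_reordering_commutes(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(2.0, 1.0, size=(40, 12))
        x = _cells_from_normalized(vals)
        perm = rng.permutation(12)
        xp = CellExpression(
            counts=x.counts.iloc[:, perm],
            cell_meta=x.cell_meta,
            normalized=x.normalized.iloc[:, perm],
        )
        a = build_metacells(x, k=3, max_shared=1, groups=x.cell_meta["sample"])
        b = build_metacells(xp, k=3, max_shared=1, groups=x.cell_meta["sample"])
        common = sorted(a.expr.columns)
        assert np.allclose(a.expr[common].to_numpy(), b.expr[common].to_numpy())


class TestSoftPower:
    def test_power_law_degrees_fit_high(self):
        rng = np.random.default_rng(0)
        k = rng.pareto(2.0, size=500) + 1.0
        assert scale_free_fit(k) >= 0.9

    def test_uniform_degrees_fit_low(self):
        rng = np.random.default_rng(1)
        k = rng.uniform(10, 11, size=500)
        assert scale_free_fit(k) < 0.9

    def test_adjacency_hand_computation_beta1(self):
        cor = np.array([[1.0, 0.5, -0.2], [0.5, 1.0, 0.1], [-0.2, 0.1, 1.0]])
        scan = scan_soft_powers_from_correlation(cor, powers=[1])
        s = (1 + cor) / 2
        np.fill_diagonal(s, 0)
        assert scan.table.loc[0, "mean_k"] == pytest.approx(s.sum(1).mean())

    def test_selection_rule_first_power_reaching_target(self):
        # heavy-tailed factor loadings make the network scale-free at some
        # moderate power; the chosen power must be the first with R^2 >= 0.9
        rng = np.random.default_rng(1)
        v = rng.random(300) ** 2
        f = rng.normal(size=400)
        data = np.outer(f, v) + rng.normal(size=(400, 300)) * np.sqrt(1 - v**2)
        cor = np.corrcoef(data, rowvar=False)
        scan = scan_soft_powers_from_correlation(cor)
        tab = scan.table
        first = int(tab.loc[tab.index[tab["r2"] >= 0.9][0], "power"])
        assert scan.chosen_power == first
        chosen_r2 = float(
            tab.loc[tab["power"] == scan.chosen_power, "r2"].iloc[0]
        )
        assert chosen_r2 >= 0.9

    def test_adjacency_monotone_in_power(self):
        rng = np.random.default_rng(2)
        cor = np.corrcoef(rng.normal(size=(30, 10)), rowvar=False)
        s = (1 + cor) / 2
        np.fill_diagonal(s, 0)
        for beta in (1, 2, 5, 12):
            a = s**beta
            assert (a <= s).all() or beta == 1
            assert ((a >= 0) & (a <= 1)).all()


class TestModules:
    def _metacells(self, seed=0, sizes=(60, 60), n_noise=80, loading=0.9,
                   n_obs=200):
        rng = np.random.default_rng(seed)
        cols = []
        for size in sizes:
            f = rng.normal(size=n_obs)
            block = loading * f[:, None] + np.sqrt(1 - loading**2) * rng.normal(
                size=(n_obs, size)
            )
            cols.append(block)
        cols.append(rng.normal(size=(n_obs, n_noise)))
        data = np.hstack(cols)
        genes = [f"g{i:03d}" for i in range(data.shape[1])]
        from oxistate.coexpression import MetacellMatrix

        expr = pd.DataFrame(
            data, index=[f"m{i}" for i in range(n_obs)], columns=genes
        )
        truth = np.r_[
            np.repeat(np.arange(len(sizes)), sizes), np.full(n_noise, -1)
        ]
        return MetacellMatrix(expr=expr, members={}, group_of={}), truth

    def test_two_planted_blocks_recovered(self):
        mc, truth = self._metacells()
        asg = detect_modules(mc, power=12, min_size=30)
        labels = asg.labels.to_numpy()
        planted = truth >= 0
        ari = adjusted_rand_score(truth[planted], labels[planted])
        assert len(asg.modules) == 2
        assert ari >= 0.9

    def test_small_block_goes_grey(self):
        mc, truth = self._metacells(sizes=(60, 10))
        asg = detect_modules(mc, power=12, min_size=30)
        small_block = asg.labels.iloc[60:70]
        assert (small_block == "grey").all()

    def test_tom_properties(self):
        rng = np.random.default_rng(1)
        cor = np.corrcoef(rng.normal(size=(50, 20)), rowvar=False)
        a = ((1 + cor) / 2) ** 6
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        assert np.allclose(np.diag(tom), 1.0)
        assert np.allclose(tom, tom.T)
        off = tom[~np.eye(20, dtype=bool)]
        assert ((off >= 0) & (off <= 1)).all()


class TestEigengenes:
    def test_rank_one_module(self):
        rng = np.random.default_rng(0)
        shared = rng.normal(size=100)
        data = np.tile(shared[:, None], (1, 6)) * rng.uniform(0.5, 2.0, 6)
        from oxistate.coexpression import MetacellMatrix, ModuleAssignment

        mc = MetacellMatrix(
            expr=pd.DataFrame(data, columns=[f"g{i}" for i in range(6)]),
            members={}, group_of={},
        )
        asg = ModuleAssignment(
            labels=pd.Series(["turquoise"] * 6, index=mc.expr.columns)
        )
        eig, varexp = module_eigengenes(mc, asg)
        z = (shared - shared.mean()) / shared.std()
        assert varexp["turquoise"] == pytest.approx(1.0)
        assert np.allclose(np.abs(eig["turquoise"]), np.abs(z), atol=1e-8)
        # orientation: positively correlated with members
        assert np.corrcoef(eig["turquoise"], data[:, 0])[0, 1] > 0

    def test_orientation_gives_nonnegative_member_correlation(self):
        # the sign rule neutralizes the arbitrary SVD sign: whatever the
        # input orientation, the eigengene correlates positively (on
        # average) with its member genes
        from oxistate.coexpression import MetacellMatrix, ModuleAssignment

        mc, _ = TestModules()._metacells(seed=3, sizes=(20,), n_noise=0)
        labels = pd.Series(["blue"] * 20, index=mc.expr.columns)
        for data in (mc.expr, -mc.expr):
            m = MetacellMatrix(expr=data, members={}, group_of={})
            eig, _ = module_eigengenes(m, ModuleAssignment(labels=labels))
            cors = [
                np.corrcoef(eig["blue"], data.iloc[:, j])[0, 1]
                for j in range(20)
            ]
            assert np.mean(cors) >= 0

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(40, 5)) + rng.normal(size=(40, 1))
        from oxistate.coexpression import MetacellMatrix, ModuleAssignment

        mc = MetacellMatrix(
            expr=pd.DataFrame(data, columns=[f"g{i}" for i in range(5)]),
            members={}, group_of={},
        )
        labels = pd.Series(["red"] * 5, index=mc.expr.columns)
        eig, _ = module_eigengenes(mc, ModuleAssignment(labels=labels))
        z = (data - data.mean(0)) / data.std(0)
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        ref = u[:, 0] / u[:, 0].std()
        diff = min(
            np.max(np.abs(eig["red"] - ref)), np.max(np.abs(eig["red"] + ref))
        )
        assert diff < 1e-8


class TestModuleStateSummary:
    def test_planted_module_orders_states(self, study, os_set):
        from oxistate.coexpression import ModuleAssignment
        from oxistate.scoring import score_cells

        cells, truth = study
        panel = score_cells(cells, os_set, seed=0)
        resp = [g for g in truth.responsive_genes if g in cells.gene_ids]
        labels = pd.Series("grey", index=cells.gene_ids)
        labels.loc[resp] = "turquoise"
        asg = ModuleAssignment(labels=labels)
        table = module_state_summary(cells, asg, panel.state)
        row = table.loc["turquoise"]
        assert row["high"] > row["transition"] > row["low"]

    def test_noise_module_state_means_close(self, study, os_set):
        from oxistate.coexpression import ModuleAssignment
        from oxistate.scoring import score_cells

        cells, truth = study
        panel = score_cells(cells, os_set, seed=0)
        rng = np.random.default_rng(8)
        planted = set(truth.responsive_genes) | set(truth.module_membership)
        noise_pool = [g for g in cells.gene_ids
                      if g not in planted and not g.startswith("MT-")]
        pick = rng.choice(noise_pool, size=50, replace=False)
        labels = pd.Series("grey", index=cells.gene_ids)
        labels.loc[pick] = "blue"
        table = module_state_summary(cells, ModuleAssignment(labels=labels),
                                     panel.state)
        row = table.loc["blue"]
        assert row.max() - row.min() < 0.05

    def test_single_module_single_state(self):
        rng = np.random.default_rng(9)
        vals = rng.gamma(2.0, 1.0, size=(30, 40))
        x = _cells_from_normalized(vals)
        from oxistate.coexpression import ModuleAssignment

        labels = pd.Series("grey", index=x.gene_ids)
        labels.iloc[:8] = "turquoise"
        states = pd.Series(["high"] * 30, index=x.cell_ids)
        with pytest.warns(UserWarning):
            table = module_state_summary(x, ModuleAssignment(labels=labels),
                                         states)
        assert table.shape == (1, 1)
        from oxistate.containers import GeneSet
        from oxistate.scoring import score_rank_u

        ref = score_rank_u(x, GeneSet("m", tuple(x.gene_ids[:8]))).mean()
        assert table.loc["turquoise", "high"] == pytest.approx(ref)


class TestPlantedModuleRecovery:
    def test_planted_modules_recovered_from_cells(self):
        cfg = SimConfig(seed=11)
        cells, truth = simulate_cells(cfg)
        cells = log_normalize(qc_filter(cells))
        mc = build_metacells(cells, groups=cells.cell_meta["sample"])
        asg = detect_modules(mc, power=6)
        mm = truth.module_membership
        genes = [g for g in mm if g in asg.labels.index]
        ari = adjusted_rand_score(
            [mm[g] for g in genes], [asg.labels[g] for g in genes]
        )
        assert ari >= 0.9
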