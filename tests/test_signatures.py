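import numpy as np
import pandas as pd
import pytest

from ecidentity import (
    ExpressionMatrix,
    GeneSetCollection,
    SignatureScoreParams,
    SimulationConfig,
    assign_subgroups,
    compare_score_groups,
    score_cells,
    simulate_expression,
    zscale_scores,
)


def matrix_with_ranks(n_genes, n_cells=1, seed=0):
    """Expression strictly decreasing with row index: gene i has rank i+1."""
    values = np.tile(
        np.linspace(1000, 1, n_genes)[:, None], (1, n_cells)
    )
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                      columns=[f"c{j}" for j in range(n_cells)])
    return ExpressionMatrix(df)


class TestScoreCells:
    def test_top_gene_single_set_scores_one(self):
        m = matrix_with_ranks(2000)
        scores = score_cells(m, GeneSetCollection({"s": ["g0"]}))
        assert scores.scores.loc["c0", "s"] == pytest.approx(1.0)

    def test_missing_gene_takes_capped_rank(self):
        m = matrix_with_ranks(2000)
        sets = GeneSetCollection({"s": ["g0", "zzz"]})
        sc = score_cells(m, sets).scores.loc["c0", "s"]
        # ranks: 1 and capped 1501 -> U = 1502 - 3 = 1499
        assert sc == pytest.approx(1 - 1499 / 3000)

    def test_single_bottom_gene_scores_floor_zero(self):
        m = matrix_with_ranks(2000)
        # g1999 sits at rank 2000 > cap -> capped 1501, U = 1500, score = 0
        sc = score_cells(m, GeneSetCollection({"s": ["g1999"]}))
        assert sc.scores.loc["c0", "s"] == pytest.approx(0.0)

    def test_five_gene_extremes(self):
        m = matrix_with_ranks(2000)
        top = GeneSetCollection({"s": [f"g{i}" for i in range(5)]})
        assert score_cells(m, top).scores.loc["c0", "s"] == pytest.approx(1.0)
        # ranks 1497..1500 and the capped 1501
        tail = GeneSetCollection({"s": [f"g{i}" for i in range(1496, 1501)]})
        sc = score_cells(m, tail).scores.loc["c0", "s"]
        r = sum([1497, 1498, 1499, 1500, 1501])
        expected = 1 - (r - 15) / (5 * 1500)
        assert sc == pytest.approx(expected)

    def test_floor_attained_when_all_genes_at_cap(self):
        m = matrix_with_ranks(2000)
        n = 7
        sets = GeneSetCollection({"s": [f"g{i}" for i in range(1993, 2000)]})
        sc = score_cells(m, sets).scores.loc["c0", "s"]
        assert sc == pytest.approx((n - 1) / (2 * 1500))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(300, 10))
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(300)],
                          columns=[f"c{j}" for j in range(10)])
        sets = GeneSetCollection({"s": [f"g{i}" for i in range(0, 60, 3)]})
        params = SignatureScoreParams(rank_cap=200)
        a = score_cells(ExpressionMatrix(df), sets, params).scores
        b = score_cells(ExpressionMatrix(np.log1p(df) ** 1.7), sets, params).scores
        pd.testing.assert_frame_equal(a, b)

    def test_empty_overlap_errors_naming_set(self):
        m = matrix_with_ranks(100)
        with pytest.raises(ValueError, match="missing_set"):
            score_cells(m, GeneSetCollection({"missing_set": ["zz1", "zz2"]}),
                        SignatureScoreParams(rank_cap=50,
                                             missing_gene_policy="drop"))

    def test_set_size_exceeding_cap_errors(self):
        m = matrix_with_ranks(100)
        sets = GeneSetCollection({"s": [f"g{i}" for i in range(60)]})
        with pytest.raises(ValueError, match="rank_cap"):
            score_cells(m, sets, SignatureScoreParams(rank_cap=50))

    def test_drop_policy_excludes_missing(self):
        m = matrix_with_ranks(2000)
        sets = GeneSetCollection({"s": ["g0", "zzz"]})
        sc = score_cells(m, sets,
                         SignatureScoreParams(missing_gene_policy="drop"))
        assert sc.scores.loc["c0", "s"] == pytest.approx(1.0)


class TestZScale:
    def make_scores(self, values):
        df = pd.DataFrame({"s": values}, index=[f"c{i}" for i in range(len(values))])
        from ecidentity.signatures import CellScores
        return CellScores(scores=df)

    def test_two_cell_example_sample_sd(self):
        z = zscale_scores(self.make_scores([0.0, 1.0])).scores["s"]
        assert z.tolist() == pytest.approx([-0.70710678, 0.70710678])

    def test_shift_invariance_and_centering(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=50)
        z1 = zscale_scores(self.make_scores(vals)).scores["s"]
        z2 = zscale_scores(self.make_scores(vals + 5.0)).scores["s"]
        assert np.allclose(z1, z2)
        assert z1.mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="s"):
            zscale_scores(self.make_scores([0.5, 0.5, 0.5]))


class TestCompareGroups:
    def test_identical_distributions_p_near_one(self):
        from ecidentity.signatures import CellScores
        vals = list(np.linspace(0, 1, 20)) * 2
        df = pd.DataFrame({"s": vals}, index=[f"c{i}" for i in range(40)])
        labels = {f"c{i}": ("a" if i < 20 else "b") for i in range(40)}
        res = compare_score_groups(CellScores(scores=df), labels, "s")
        assert res.p_value > 0.95

    def test_relabeling_flips_sign_keeps_p(self):
        from ecidentity.signatures import CellScores
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"s": rng.normal(size=40)},
                          index=[f"c{i}" for i in range(40)])
        df.iloc[:20, 0] += 1.0
        lab1 = {f"c{i}": ("a" if i < 20 else "b") for i in range(40)}
        lab2 = {f"c{i}": ("b" if i < 20 else "a") for i in range(40)}
        r1 = compare_score_groups(CellScores(scores=df), lab1, "s")
        r2 = compare_score_groups(CellScores(scores=df), lab2, "s")
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_planted_shift_detected(self):
        cfg = SimulationConfig(seed=3, n_cells=600,
                               subgroup_proportions=(1 / 3, 1 / 3, 1 / 3))
        matrix, sets, truth = simulate_expression(cfg)
        scores = score_cells(matrix, sets)
        two = {c: g for c, g in truth.cell_subgroups.items()
               if g in ("EC-like", "mesenchymal-like")}
        res = compare_score_groups(scores, two, "mesenchymal-like")
        assert res.p_value < 1e-6

    def test_requires_two_groups(self):
        from ecidentity.signatures import CellScores
        df = pd.DataFrame({"s": [0.1, 0.2]}, index=["c1", "c2"])
        with pytest.raises(ValueError, match="two groups"):
            compare_score_groups(CellScores(scores=df), {"c1": "a", "c2": "a"}, "s")


class TestAssignSubgroups:
    def test_dominant_marker_wins(self):
        # cells expressing only one set's genes at the top
        genes = [f"g{i}" for i in range(60)]
        data = np.ones((60, 3))
        data[:10, 0] = 100.0   # cell0: set A genes on top
        data[10:20, 1] = 100.0  # cell1: set B genes on top
        data[20:30, 2] = 100.0  # cell2: set C genes on top
        df = pd.DataFrame(data, index=genes, columns=["c0", "c1", "c2"])
        sets = GeneSetCollection({
            "A": genes[:10], "B": genes[10:20], "C": genes[20:30],
        })
        asg = assign_subgroups(ExpressionMatrix(df), sets,
                               SignatureScoreParams(rank_cap=40))
        assert asg.labels == {"c0": "A", "c1": "B", "c2": "C"}

    def test_three_population_mixture_accuracy(self):
        hits, total = 0, 0
        for seed in range(3):
            cfg = SimulationConfig(seed=seed)
            matrix, sets, truth = simulate_expression(cfg)
            asg = assign_subgroups(matrix, sets)
            for cell, want in truth.cell_subgroups.items():
                hits += asg.labels[cell] == want
                total += 1
        assert hits / total >= 0.9

    def test_cell_order_invariance(self):
        cfg = SimulationConfig(seed=1, n_cells=60, signature_set_size=10,
                               n_genes=200)
        matrix, sets, truth = simulate_expression(cfg)
        asg1 = assign_subgroups(matrix, sets)
        shuffled = ExpressionMatrix(
            matrix.values.iloc[:, ::-1], matrix.cell_labels
        )
        asg2 = assign_subgroups(shuffled, sets)
        assert asg1.labels == asg2.labels

    def test_two_set_margin_rule_labels_transitional(self):
        genes = [f"g{i}" for i in range(40)]
        data = np.ones((40, 3))
        data[:10, 0] = 100.0            # c0 endothelial-dominant
        data[10:20, 1] = 100.0          # c1 mesenchymal-dominant
        data[:10, 2] = 50.0             # c2 balanced
        data[10:20, 2] = 50.0
        df = pd.DataFrame(data, index=genes, columns=["c0", "c1", "c2"])
        sets = GeneSetCollection({"EC-like": genes[:10],
                                  "mesenchymal-like": genes[10:20]})
        asg = assign_subgroups(ExpressionMatrix(df), sets,
                               SignatureScoreParams(rank_cap=30))
        assert asg.labels["c0"] == "EC-like"
        assert asg.labels["c1"] == "mesenchymal-like"
        assert asg.labels["c2"] == "EndoMT"

    def test_wrong_set_count_errors(self):
        m = matrix_with_ranks(100)
        with pytest.raises(ValueError):
            assign_subgroups(m, GeneSetCollection({"only": ["g0"]}),
                             SignatureScoreParams(rank_cap=50))


class TestStepwiseDecrease:
    def test_focal_gene_decreases_and_repressed_set_peaks_mesenchymal(self):
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, n_cells=450,
                                   subgroup_proportions=(1 / 3, 1 / 3, 1 / 3))
            matrix, sets, truth = simulate_expression(cfg)
            labels = truth.cell_subgroups
            order = ["EC-like", "EndoMT", "mesenchymal-like"]
            focal = matrix.values.loc[truth.focal_gene]
            means = [
                focal[[c for c in labels if labels[c] == g]].mean() for g in order
            ]
            assert means[0] > means[1] > means[2]
            scores = score_cells(matrix, sets)
            two = {c: g for c, g in labels.items()
                   if g in ("EC-like", "mesenchymal-like")}
            res = compare_score_groups(scores, two, "mesenchymal-like")
            assert res.p_value < 0.01
            assert res.summary["mean_y"] > res.summary["mean_x"]  # mes > EC
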