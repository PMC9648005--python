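import warnings

import numpy as np
import pandas as pd
import pytest

from chondro.fixtures import ExpressionGenSpec, FixtureSpec, make_fixture, simulate_expression
from chondro.grn import (
    ConsensusEdge,
    EdgeScoreMatrix,
    ExpressionMatrix,
    cluster_qc,
    consensus,
    correct_batch,
    integrate_edges,
    quantile_normalize,
    score_edges,
)
from chondro.grn.consensus import method_threshold


def _matrix(values, genes=None, samples=None, batch=None, phenotype=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    samples = samples or [f"s{j}" for j in range(len(values[0]))]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        batch=pd.Series(batch, index=samples) if batch is not None else None,
        phenotype=pd.Series(phenotype, index=samples) if phenotype is not None else None,
    )


class TestExpressionMatrix:
    def test_rejects_missing_values(self):
        with pytest.raises(ValueError):
            _matrix([[1.0, np.nan]])

    def test_rejects_duplicate_genes(self):
        with pytest.raises(ValueError):
            _matrix([[1.0], [2.0]], genes=["g", "g"])

    def test_file_round_trip(self, tmp_path):
        m = _matrix([[1.0, 2.0], [3.0, 4.0]], batch=["b0", "b1"], phenotype=["OA", "WT"])
        mat, ann = str(tmp_path / "m.tsv"), str(tmp_path / "ann.csv")
        m.to_files(mat, ann)
        again = ExpressionMatrix.from_files(mat, ann)
        pd.testing.assert_frame_equal(again.values, m.values)
        assert list(again.batch) == ["b0", "b1"]
        assert list(again.phenotype) == ["OA", "WT"]


class TestQuantileNormalize:
    def test_hand_computed_reference(self):
        m = _matrix([[2.0, 1.0, 3.0], [4.0, 5.0, 8.0], [6.0, 9.0, 7.0]])
        out = quantile_normalize(m).values.to_numpy()
        ref = np.array([2.0, 16 / 3, 23 / 3])
        expected = np.column_stack([ref, ref, [ref[0], ref[2], ref[1]]])
        np.testing.assert_allclose(out, expected)

    def test_identical_distributions_fixed_point(self):
        m = _matrix([[1.0, 2.0], [3.0, 1.0], [2.0, 3.0]])
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values, check_exact=False)

    def test_constant_matrix_unchanged(self):
        m = _matrix([[5.0, 5.0], [5.0, 5.0]])
        np.testing.assert_allclose(quantile_normalize(m).values.to_numpy(), 5.0)

    def test_ties_get_average_reference(self):
        m = _matrix([[1.0, 4.0], [1.0, 2.0], [3.0, 6.0]])
        out = quantile_normalize(m).values.to_numpy()
        # Column sorted values must be identical across columns afterwards.
        np.testing.assert_allclose(np.sort(out[:, 0])[-1], np.sort(out[:, 1])[-1])

    def test_columns_share_sorted_values_property(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(30, 8)).tolist())
        out = quantile_normalize(m).values.to_numpy()
        first = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), first)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            quantile_normalize(_matrix([[1.0]]))


class TestCorrectBatch:
    def test_single_batch_identity(self):
        m = _matrix([[1.0, 2.0, 3.0]], batch=["b", "b", "b"])
        pd.testing.assert_frame_equal(correct_batch(m).values, m.values)

    def test_requires_batch_labels(self):
        with pytest.raises(ValueError):
            correct_batch(_matrix([[1.0, 2.0]]))

    def test_small_batch_errors(self):
        m = _matrix([[1.0, 2.0, 3.0]], batch=["a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            correct_batch(m)

    def test_noiseless_location_shift_aligned(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=5)
        shift = rng.normal(scale=3.0, size=5)
        values = np.column_stack([base, base, base + shift, base + shift])
        m = _matrix(values.tolist(), batch=["a", "a", "b", "b"])
        out = correct_batch(m).values.to_numpy()
        pooled_sd = values.std()
        gap = np.abs(out[:, :2].mean(axis=1) - out[:, 2:].mean(axis=1))
        assert np.all(gap < 1e-6 * pooled_sd)

    def test_pooled_gene_mean_preserved(self):
        matrix, _ = simulate_expression(
            ExpressionGenSpec.random(n_genes=10, n_tfs=3, seed=3, n_samples=40, n_batches=2)
        )
        out = correct_batch(quantile_normalize(matrix))
        np.testing.assert_allclose(
            out.values.mean(axis=1), quantile_normalize(matrix).values.mean(axis=1), rtol=1e-9
        )

    def test_planted_shift_variance_reduced(self):
        matrix, _ = simulate_expression(
            ExpressionGenSpec.random(
                n_genes=15, n_tfs=4, seed=2, n_samples=80, n_batches=2, batch_shift_sd=3.0
            )
        )
        out = correct_batch(matrix)

        def between_fraction(m):
            X = m.values.to_numpy()
            labels = m.batch.to_numpy()
            grand = X.mean(axis=1, keepdims=True)
            between = sum(
                (labels == b).sum() * (X[:, labels == b].mean(axis=1, keepdims=True) - grand) ** 2
                for b in dict.fromkeys(labels)
            ).sum()
            total = ((X - grand) ** 2).sum()
            return between / total

        assert between_fraction(matrix) / between_fraction(out) >= 5.0


class TestClusterQC:
    def test_separated_blobs_perfect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.2, size=(10, 12))
        b = rng.normal(5.0, 0.2, size=(10, 12))
        values = np.hstack([a, b])
        m = _matrix(values.tolist(), phenotype=["OA"] * 12 + ["WT"] * 12)
        acc = cluster_qc(m, n_groups=2)
        assert acc == {"OA": 1.0, "WT": 1.0}

    def test_permuted_labels_near_baseline(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 0.2, size=(10, 20))
        b = rng.normal(5.0, 0.2, size=(10, 20))
        values = np.hstack([a, b])
        phen = np.array(["OA"] * 20 + ["WT"] * 20)
        accs = []
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(40)
            m = _matrix(values.tolist(), phenotype=list(phen[perm]))
            acc = cluster_qc(m, n_groups=2)
            accs.append(np.mean(list(acc.values())))
        # Random labels against a fixed 20/20 split: accuracy hovers around
        # the majority-group baseline, far from perfect separation.
        assert 0.3 < np.mean(accs) < 0.8

    def test_requires_phenotype(self):
        with pytest.raises(ValueError):
            cluster_qc(_matrix([[1.0, 2.0]]))

    def test_too_many_groups(self):
        m = _matrix([[1.0, 2.0]], phenotype=["OA", "WT"])
        with pytest.raises(ValueError):
            cluster_qc(m, n_groups=5)


class TestScoreEdges:
    @pytest.fixture(scope="class")
    @staticmethod
    def data():
        spec = ExpressionGenSpec.random(
            n_genes=14, n_tfs=4, targets_per_tf=3, seed=0, n_samples=120, n_batches=1
        )
        matrix, truth = simulate_expression(spec)
        return spec, matrix, truth

    @pytest.mark.parametrize("method", ["mi_dpi", "tree_importance", "stability_regression"])
    def test_shape_contract(self, data, method):
        spec, matrix, _ = data
        result = score_edges(matrix, spec.tf_ids, method, seed=0)
        assert result.scores.shape == (len(spec.tf_ids), matrix.n_genes)
        for tf in spec.tf_ids:
            assert np.isnan(result.scores.loc[tf, tf])
        finite = result.finite_values()
        assert np.all(finite >= 0)

    @pytest.mark.parametrize("method", ["mi_dpi", "tree_importance", "stability_regression"])
    def test_aupr_beats_baseline(self, data, method):
        from sklearn.metrics import average_precision_score

        spec, matrix, truth = data
        result = score_edges(matrix, spec.tf_ids, method, seed=0)
        true_set = {(s, t) for s, t, _ in truth}
        y, s = [], []
        for tf in result.tfs:
            for gene in result.genes:
                if tf == gene:
                    continue
                y.append((tf, gene) in true_set)
                s.append(result.scores.loc[tf, gene])
        aupr = average_precision_score(y, s)
        assert aupr > 3 * np.mean(y)

    def test_unknown_method(self, data):
        spec, matrix, _ = data
        with pytest.raises(ValueError):
            score_edges(matrix, spec.tf_ids, "correlation")

    def test_unknown_tf(self, data):
        _, matrix, _ = data
        with pytest.raises(ValueError):
            score_edges(matrix, ["NOPE"], "mi_dpi")

    def test_too_few_samples(self):
        m = _matrix(np.random.default_rng(0).normal(size=(3, 5)).tolist())
        with pytest.raises(ValueError, match="10 samples"):
            score_edges(m, ["g0"], "mi_dpi")

    def test_constant_gene_warns_and_scores_zero(self, data):
        spec, matrix, _ = data
        values = matrix.values.copy()
        values.iloc[-1] = 1.0
        flat = ExpressionMatrix(values=values)
        gene = values.index[-1]
        with pytest.warns(UserWarning, match="constant"):
            result = score_edges(flat, spec.tf_ids, "tree_importance", seed=0)
        assert (result.scores[gene].dropna() == 0).all()

    def test_seed_determinism(self, data):
        spec, matrix, _ = data
        a = score_edges(matrix, spec.tf_ids, "stability_regression", seed=11)
        b = score_edges(matrix, spec.tf_ids, "stability_regression", seed=11)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_noise_gene_below_tree_threshold(self):
        # A gene independent of every TF stays under the mean-minus-SD
        # threshold of the forest scorer in >= 90% of seeds.
        hits = 0
        for seed in range(10):
            spec = ExpressionGenSpec.random(
                n_genes=19, n_tfs=5, targets_per_tf=13, seed=seed, n_samples=200, n_batches=1
            )
            matrix, _ = simulate_expression(spec)
            rng = np.random.default_rng(seed + 1000)
            values = matrix.values.copy()
            values.loc["NOISE"] = rng.normal(size=matrix.n_samples)
            m2 = ExpressionMatrix(values=values)
            result = score_edges(m2, spec.tf_ids, "tree_importance", seed=seed)
            if result.scores["NOISE"].max() <= method_threshold(result):
                hits += 1
        assert hits >= 9


def _score_matrix(df, method):
    return EdgeScoreMatrix(scores=df, method=method)


class TestConsensus:
    @pytest.fixture()
    def expression(self):
        rng = np.random.default_rng(0)
        tf = rng.normal(size=40)
        return _matrix(
            [list(tf), list(2 * tf + rng.normal(0, 0.1, 40)), list(-tf + rng.normal(0, 0.1, 40))],
            genes=["TF", "UP", "DOWN"],
        )

    def _scores(self, tf_up, tf_down, baseline=0.0):
        df = pd.DataFrame(
            [[np.nan, tf_up, tf_down]], index=["TF"], columns=["TF", "UP", "DOWN"]
        )
        df.iloc[0] = [np.nan, tf_up, tf_down]
        return df

    def test_edge_passing_all_methods_kept(self, expression):
        mats = [
            _score_matrix(self._scores(1.0, 0.1), m)
            for m in ("mi_dpi", "tree_importance", "stability_regression")
        ]
        edges = consensus(mats, expression)
        assert [(e.source, e.target) for e in edges] == [("TF", "UP")]
        assert edges[0].sign == 1
        assert edges[0].per_method_pass == (True, True, True)

    def test_edge_passing_two_methods_dropped(self, expression):
        mats = [
            _score_matrix(self._scores(1.0, 0.1), "mi_dpi"),
            _score_matrix(self._scores(1.0, 0.1), "tree_importance"),
            _score_matrix(self._scores(0.1, 1.0), "stability_regression"),
        ]
        assert consensus(mats, expression) == []

    def test_negative_spearman_sign(self, expression):
        mats = [
            _score_matrix(self._scores(0.1, 1.0), m)
            for m in ("mi_dpi", "tree_importance", "stability_regression")
        ]
        edges = consensus(mats, expression)
        assert [(e.source, e.target, e.sign) for e in edges] == [("TF", "DOWN", -1)]
        assert edges[0].spearman < 0

    def test_zero_variance_pair_dropped_with_warning(self):
        # G is constant, so its Spearman sign is undefined; the edge passes
        # every threshold but must be dropped at the signing step.
        m = _matrix(
            [list(range(12)), [1.0] * 12, list(range(12))], genes=["TF", "G", "H"]
        )
        df = pd.DataFrame([[np.nan, 1.0, 0.0]], index=["TF"], columns=["TF", "G", "H"])
        mats = [_score_matrix(df, meth) for meth in ("a", "b", "c")]
        with pytest.warns(UserWarning, match="zero-variance"):
            assert consensus(mats, m) == []

    def test_mismatched_indexing_errors(self, expression):
        df1 = pd.DataFrame([[np.nan, 1.0, 1.0]], index=["TF"], columns=["TF", "UP", "DOWN"])
        df2 = pd.DataFrame([[1.0, np.nan]], index=["UP"], columns=["UP", "TF"])
        with pytest.raises(ValueError):
            consensus([_score_matrix(df1, "a"), _score_matrix(df2, "b")], expression)

    def test_monotonicity(self, expression):
        rng = np.random.default_rng(5)
        genes = ["TF", "UP", "DOWN"]
        dfs = []
        for _ in range(3):
            df = pd.DataFrame(
                rng.uniform(0, 1, size=(1, 3)), index=["TF"], columns=genes
            )
            df.loc["TF", "TF"] = np.nan
            dfs.append(df)
        base_edges = {
            (e.source, e.target)
            for e in consensus([_score_matrix(d, str(i)) for i, d in enumerate(dfs)], expression)
        }
        # Raising one method's score for an already-passing edge never
        # removes a consensus edge.
        boosted = [d.copy() for d in dfs]
        boosted[0].loc["TF", "UP"] = boosted[0].loc["TF", "UP"] + 0.5
        new_edges = {
            (e.source, e.target)
            for e in consensus(
                [_score_matrix(d, str(i)) for i, d in enumerate(boosted)], expression
            )
        }
        kept = {e for e in base_edges if e == ("TF", "UP")}
        assert kept <= new_edges


class TestIntegrateEdges:
    def test_append_and_rule_term(self, mini):
        edges = [
            ConsensusEdge(
                source="SOX9", target="COL-X", per_method_pass=(True,) * 3, spearman=-0.8, sign=-1
            )
        ]
        out = integrate_edges(mini, edges)
        assert out.n_interactions == mini.n_interactions + 1
        new = [i for i in out.interactions if i.provenance == "inferred"]
        assert len(new) == 1 and new[0].layer == "slow" and new[0].sign == -1
        assert ("SOX9", -1) in out.rule("COL-X", "slow").terms

    def test_empty_edge_list_identity(self, mini):
        assert integrate_edges(mini, []) == mini

    def test_duplicate_skipped_with_report(self, mini):
        edges = [
            ConsensusEdge(
                source="SOX9", target="COL-II", per_method_pass=(True,) * 3, spearman=0.9, sign=1
            )
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            out = integrate_edges(mini, edges)
        assert out.n_interactions == mini.n_interactions
        assert out.metadata["integration_report"]["skipped_duplicates"] == [("SOX9", "COL-II")]

    def test_unmappable_gene_errors(self, mini):
        edges = [
            ConsensusEdge(
                source="Sox9_gene", target="COL-X", per_method_pass=(True,) * 3, spearman=0.5, sign=1
            )
        ]
        with pytest.raises(KeyError):
            integrate_edges(mini, edges)
        out = integrate_edges(mini, edges, mapping={"Sox9_gene": "SOX9"})
        assert out.n_interactions == mini.n_interactions + 1
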