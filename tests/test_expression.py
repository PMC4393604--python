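"""-ddCT quantification, DE calls, expression clustering, enrichment."""

import numpy as np
import pandas as pd
import pytest

from bzipkit import expression as ex
from bzipkit import synth
from bzipkit.io import CtTable


def _ct_rows(gene, cond, cts):
    return [
        {"gene_id": gene, "condition_id": cond, "replicate": r + 1, "ct": ct}
        for r, ct in enumerate(cts)
    ]


def _simple_table(target_treat=20.0, ref_treat=18.0, target_cal=20.0, ref_cal=18.0):
    rows = (
        _ct_rows("REF", "control", [ref_cal] * 3)
        + _ct_rows("REF", "treat", [ref_treat] * 3)
        + _ct_rows("g1", "control", [target_cal] * 3)
        + _ct_rows("g1", "treat", [target_treat] * 3)
    )
    return CtTable(pd.DataFrame(rows), "REF", "control")


class TestDeltaDeltaCt:
    def test_equal_dct_gives_zero(self):
        m = ex.delta_delta_ct(_simple_table())
        assert m.minus_ddct.at["g1", "treat"] == 0.0
        assert m.minus_ddct.at["g1", "control"] == 0.0

    def test_one_cycle_drop_is_plus_one(self):
        m = ex.delta_delta_ct(_simple_table(target_treat=19.0))
        assert m.minus_ddct.at["g1", "treat"] == pytest.approx(1.0)

    def test_planted_effect_recovered_under_noise(self, rng):
        design = synth.ExpressionDesign(n_genes=12, noise_sd=0.1)
        ct, _, effects, _ = synth.gen_ct_table(design, seed=61)
        m = ex.delta_delta_ct(ct)
        est = m.minus_ddct[effects.columns]
        # replicate-mean estimate sd = noise * sqrt(2/replicates)
        sd = 0.1 * np.sqrt(2 / design.replicates)
        assert (np.abs(est - effects) < 3 * sd).all().all()


class TestFoldChanges:
    @pytest.mark.parametrize("mddct,fold", [(1.0, 2.0), (0.0, 1.0), (-1.0, 0.5)])
    def test_mapping(self, mddct, fold):
        m = ex.delta_delta_ct(_simple_table(target_treat=20.0 - mddct))
        assert ex.fold_changes(m).at["g1", "treat"] == pytest.approx(fold)

    def test_calibrator_column_exactly_one(self):
        design = synth.ExpressionDesign(n_genes=10)
        ct, *_ = synth.gen_ct_table(design, seed=62)
        folds = ex.fold_changes(ex.delta_delta_ct(ct))
        assert (folds["control"] == 1.0).all()


class TestDeCalls:
    def _matrix(self, treat_cts):
        rows = (
            _ct_rows("REF", "control", [18.0] * 3)
            + _ct_rows("REF", "treat", [18.0] * 3)
            + _ct_rows("g1", "control", [20.0, 20.05, 19.95])
            + _ct_rows("g1", "treat", treat_cts)
        )
        return ex.delta_delta_ct(CtTable(pd.DataFrame(rows), "REF", "control"))

    def test_strong_induction_up(self):
        calls = ex.de_calls(self._matrix([18.0, 18.02, 17.98]))
        assert calls.iloc[0].call == "up"

    def test_high_variance_not_significant(self):
        calls = ex.de_calls(self._matrix([14.0, 22.0, 18.0]))
        assert calls.iloc[0].call == "ns"

    def test_strong_repression_down(self):
        calls = ex.de_calls(self._matrix([22.0, 21.98, 22.02]))
        assert calls.iloc[0].call == "down"

    def test_zero_noise_calls_match_planted_design(self):
        design = synth.ExpressionDesign(noise_sd=0.0)
        ct, _, effects, _ = synth.gen_ct_table(design, seed=63)
        calls = ex.de_calls(ex.delta_delta_ct(ct)).set_index(["gene", "condition"])
        for (g, c), effect in effects.stack().items():
            expected = "up" if effect >= 1 else ("down" if effect <= -1 else "ns")
            assert calls.loc[(g, c), "call"] == expected

    def test_tightening_fold_cutoff_monotone(self):
        design = synth.ExpressionDesign(n_genes=24, noise_sd=0.4)
        ct, *_ = synth.gen_ct_table(design, seed=64)
        m = ex.delta_delta_ct(ct)
        loose = ex.de_calls(m, up_fold=1.5, down_fold=1 / 1.5)
        tight = ex.de_calls(m, up_fold=3.0, down_fold=1 / 3.0)
        n_loose = (loose.call != "ns").sum()
        n_tight = (tight.call != "ns").sum()
        assert n_tight <= n_loose


class TestClustering:
    def test_two_anticorrelated_blocks_recovered(self):
        conds = [f"c{i}" for i in range(6)]
        up = [1.0, 2.0, 1.5, -1.0, -2.0, -1.5]
        genes = {f"gU{i}": up for i in range(5)} | {
            f"gD{i}": [-v for v in up] for i in range(5)
        }
        m = ex.ExpressionMatrix(
            pd.DataFrame(genes, index=conds).T,
            pd.DataFrame(columns=["gene_id", "condition_id", "replicate", "dct"]),
            "REF", "c0",
        )
        clusters = ex.cluster_expression(m, k=2)
        labels = clusters.labels
        assert len(set(labels[[f"gU{i}" for i in range(5)]])) == 1
        assert len(set(labels[[f"gD{i}" for i in range(5)]])) == 1
        assert labels["gU0"] != labels["gD0"]

    def test_planted_four_clusters_high_ari(self):
        from sklearn.metrics import adjusted_rand_score

        design = synth.ExpressionDesign()  # 96 genes, sep 2, sd 0.5, 3 reps
        ct, planted, _, _ = synth.gen_ct_table(design, seed=65)
        clusters = ex.cluster_expression(ex.delta_delta_ct(ct), k=4)
        ari = adjusted_rand_score(
            planted[clusters.labels.index], clusters.labels
        )
        assert ari > 0.9

    def test_k_equals_n_singletons(self):
        design = synth.ExpressionDesign(n_genes=6)
        ct, *_ = synth.gen_ct_table(design, seed=66)
        m = ex.delta_delta_ct(ct)
        clusters = ex.cluster_expression(m, k=6)
        assert clusters.labels.nunique() == 6

    def test_constant_gene_euclidean_fallback_flagged(self):
        conds = [f"c{i}" for i in range(5)]
        data = {
            "g1": [1, 2, 3, 4, 5],
            "g2": [1.1, 2, 3, 4, 5.2],
            "g3": [5, 4, 3, 2, 1],
            "g4": [5, 4.1, 3, 1.9, 1],
            "flat": [2, 2, 2, 2, 2],
        }
        m = ex.ExpressionMatrix(
            pd.DataFrame(data, index=conds).T,
            pd.DataFrame(columns=["gene_id", "condition_id", "replicate", "dct"]),
            "REF", "c0",
        )
        clusters = ex.cluster_expression(m, k=2)
        assert clusters.flags["euclidean_fallback_genes"] == ["flat"]
        assert "flat" in clusters.labels.index

    def test_labels_ordered_by_descending_size(self):
        design = synth.ExpressionDesign()
        ct, *_ = synth.gen_ct_table(design, seed=67)
        clusters = ex.cluster_expression(ex.delta_delta_ct(ct), k=4)
        sizes = clusters.labels.value_counts()
        labels_in_order = ["I", "II", "III", "IV"]
        assert list(sizes.index) == sorted(
            sizes.index, key=labels_in_order.index
        ) or sizes.is_monotonic_decreasing


class TestPatternEnrichment:
    def _clusters(self, mapping):
        labels = pd.Series(mapping, name="cluster")
        return ex.ExpressionCluster(labels, np.zeros((0, 4)), k=2)

    def test_all_pattern_b_in_one_cluster(self):
        clusters = self._clusters({"g1": "II", "g2": "II", "g3": "I"})
        tab = ex.pattern_enrichment(clusters, {"g1": "b", "g2": "b", "g3": "a"})
        assert tab.loc["b", "II"] == 1.0

    def test_rows_sum_to_one(self):
        clusters = self._clusters({f"g{i}": "I" if i % 2 else "II" for i in range(10)})
        patterns = {f"g{i}": "abeh"[i % 4] for i in range(10)}
        tab = ex.pattern_enrichment(clusters, patterns)
        assert np.allclose(tab.sum(axis=1), 1.0)

    def test_genes_without_pattern_excluded(self):
        clusters = self._clusters({"g1": "I", "g2": "II"})
        tab = ex.pattern_enrichment(clusters, {"g1": "a"})
        assert list(tab.index) == ["a"]
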