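"""Differential expression, DEG selection and trajectory clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from marmodev._util import AnalysisError
from marmodev.synthetic import ExprSimConfig, gen_expression
from marmodev.transcriptomics import (ExpressionStudy, age_overlap_fisher,
                                      cluster_trajectories, collapse_probes,
                                      deg_pipeline, diff_expression,
                                      filter_expressed, geneset_enrichment,
                                      select_degs)


def _study(matrix_rows, n_per_cell=3, ages=("0M",)):
    cols, meta = [], []
    for age in ages:
        for group in ("UE", "VPA"):
            for i in range(n_per_cell):
                sid = f"{age}_{group}_{i}"
                cols.append(sid)
                meta.append((sid, age, group, "8"))
    matrix = pd.DataFrame.from_dict(matrix_rows, orient="index",
                                    columns=cols)
    metadata = pd.DataFrame(meta, columns=["sample_id", "age", "group",
                                           "area"]).set_index("sample_id")
    return ExpressionStudy(matrix=matrix, metadata=metadata)


class TestExpressedFilter:
    def test_strict_threshold_boundary(self):
        study = _study({"hi": [5.1] * 6, "lo": [4.9] * 6, "edge": [5.0] * 6})
        flags = filter_expressed(study)
        assert flags["hi"] and not flags["lo"] and not flags["edge"]


def _bh_oracle(p):
    """Step-up Benjamini-Hochberg: min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestDiffExpression:
    def test_bh_oracle_frozen_example(self):
        np.testing.assert_allclose(_bh_oracle([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_identical_groups_give_zero_logfc_and_p_one(self):
        study = _study({f"g{i}": [6.0, 7.0, 8.0] * 2 for i in range(4)})
        out = diff_expression(study, "0M")
        np.testing.assert_allclose(out["logFC_0M"], 0.0)
        np.testing.assert_allclose(out["p_raw_0M"], 1.0)

    def test_degenerate_zero_variance_unequal_means_flagged(self):
        study = _study({"flat": [5.5] * 3 + [6.5] * 3,
                        "normal": [6.0, 7.0, 8.0, 6.1, 7.1, 8.1]})
        out = diff_expression(study, "0M")
        assert math.isnan(out.loc["flat", "p_raw_0M"])
        assert math.isnan(out.loc["flat", "p_adj_0M"])
        assert not math.isnan(out.loc["normal", "p_adj_0M"])

    def test_adjustment_matches_bh_oracle(self):
        rng = np.random.default_rng(0)
        study = _study({f"g{i}": rng.normal(7, 1, 6) for i in range(40)})
        out = diff_expression(study, "0M")
        np.testing.assert_allclose(out["p_adj_0M"],
                                   _bh_oracle(out["p_raw_0M"]), rtol=1e-12)

    def test_bh_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(1)
        study = _study({f"g{i}": rng.normal(7, 1, 6) for i in range(30)})
        out = diff_expression(study, "0M").sort_values("p_raw_0M")
        assert (out["p_adj_0M"].to_numpy() >= out["p_raw_0M"].to_numpy()
                - 1e-15).all()
        assert (np.diff(out["p_adj_0M"].to_numpy()) >= -1e-15).all()

    def test_requires_two_samples_per_group(self):
        study = _study({"g": [6.0, 7.0]}, n_per_cell=1)
        with pytest.raises(AnalysisError, match="2 samples"):
            diff_expression(study, "0M")


class TestCollapseProbes:
    @staticmethod
    def _table():
        return pd.DataFrame({
            "logFC_0M": [0.5, 0.1, 0.9],
            "p_raw_0M": [0.001, 0.05, 0.001],
            "p_adj_0M": [0.01, 0.2, 0.01],
        }, index=["probeA", "probeB", "probeC"])

    def test_lowest_padj_probe_wins(self):
        mapping = pd.Series({"probeA": "GENE1", "probeB": "GENE1"})
        out = collapse_probes(self._table(), mapping)
        assert out.loc["GENE1", "logFC_0M"] == 0.5

    def test_tie_broken_by_raw_p_then_probe_id(self):
        table = self._table()
        mapping = pd.Series({"probeA": "GENE1", "probeC": "GENE1"})
        table.loc["probeC", "p_raw_0M"] = 0.0005  # wins the tie on raw p
        out = collapse_probes(table, mapping)
        assert out.loc["GENE1", "logFC_0M"] == 0.9
        table.loc["probeC", "p_raw_0M"] = 0.001  # full tie: probeA by id
        out = collapse_probes(table, mapping)
        assert out.loc["GENE1", "logFC_0M"] == 0.5

    def test_unmapped_probe_dropped(self):
        mapping = pd.Series({"probeA": "GENE1"})
        out = collapse_probes(self._table(), mapping)
        assert list(out.index) == ["GENE1"]


class TestSelectDegs:
    def test_rule_boundaries(self):
        table = pd.DataFrame({
            "logFC_3M": [0.5, 0.4, 0.9],
            "p_adj_3M": [0.01, 0.001, 0.06],
        }, index=["hit", "at_logfc_boundary", "at_p_boundary"])
        flags = select_degs(table)
        assert flags["hit"]
        assert not flags["at_logfc_boundary"]  # strict >0.4
        assert not flags["at_p_boundary"]      # strict <0.05

    def test_either_age_suffices(self):
        table = pd.DataFrame({
            "logFC_0M": [0.0], "p_adj_0M": [0.9],
            "logFC_6M": [-0.8], "p_adj_6M": [0.001]}, index=["g"])
        assert select_degs(table)["g"]

    def test_equivalent_to_brute_force_row_scan(self):
        rng = np.random.default_rng(2)
        n = 300
        table = pd.DataFrame(
            {f"logFC_{a}": rng.normal(0, 0.5, n) for a in ("0M", "3M", "6M")}
            | {f"p_adj_{a}": rng.uniform(0, 0.2, n)
               for a in ("0M", "3M", "6M")},
            index=[f"g{i}" for i in range(n)])
        flags = select_degs(table)
        for gene, row in table.iterrows():
            expected = any(abs(row[f"logFC_{a}"]) > 0.4
                           and row[f"p_adj_{a}"] < 0.05
                           for a in ("0M", "3M", "6M"))
            assert flags[gene] == expected


class TestClustering:
    def test_single_shared_trajectory_selects_k_one(self):
        logfc = pd.DataFrame([[0.5, -0.2, 0.1]] * 30,
                             columns=["logFC_0M", "logFC_3M", "logFC_6M"])
        model = cluster_trajectories(logfc, seed=0)
        assert model.k == 1

    def test_three_planted_noiseless_clusters(self):
        centers = [(-0.8, -0.2, -0.1), (-0.1, -0.7, -0.3), (0.1, 0.7, 0.3)]
        rows, labels = [], []
        for c, center in enumerate(centers, start=1):
            rows += [center] * 25
            labels += [c] * 25
        logfc = pd.DataFrame(rows, columns=["logFC_0M", "logFC_3M",
                                            "logFC_6M"])
        model = cluster_trajectories(logfc, seed=0)
        assert model.k == 3
        assert adjusted_rand_score(labels, model.assignments) == 1.0
        # AIC strictly increases past the planted k on noiseless data
        aic = model.aic_by_k
        assert (aic.loc[4:].diff().dropna() > 0).all()
        assert aic.loc[3] < aic.loc[4]

    def test_labels_ordered_by_value_at_birth(self):
        rng = np.random.default_rng(0)
        centers = [(0.6, 0.0, 0.0), (-0.9, 0.0, 0.0), (-0.1, 0.5, 0.2)]
        rows = [np.asarray(c) + 0.02 * rng.standard_normal(3)
                for c in centers for _ in range(20)]
        logfc = pd.DataFrame(rows, columns=["logFC_0M", "logFC_3M",
                                            "logFC_6M"])
        model = cluster_trajectories(logfc, k_range=range(1, 5), seed=1)
        assert model.k == 3
        c0 = model.centroids["logFC_0M"]
        assert c0.loc[1] < c0.loc[2] < c0.loc[3]
        # a different seed converges to the same labeling after ordering
        model2 = cluster_trajectories(logfc, k_range=range(1, 5), seed=99)
        pd.testing.assert_series_equal(model.assignments, model2.assignments)

    def test_fewer_trajectories_than_k_skips_those_k(self):
        logfc = pd.DataFrame([[0.5, 0.1, 0.0]] * 4,
                             columns=["logFC_0M", "logFC_3M", "logFC_6M"])
        model = cluster_trajectories(logfc, k_range=range(1, 9), seed=0)
        assert set(model.aic_by_k.index) <= {1, 2, 3, 4}


def _hypergeom_tail(both, set_a_size, set_b_size, universe_size):
    """P(overlap >= both) by direct enumeration of the hypergeometric."""
    total = math.comb(universe_size, set_b_size)
    acc = 0
    for k in range(both, min(set_a_size, set_b_size) + 1):
        acc += (math.comb(set_a_size, k)
                * math.comb(universe_size - set_a_size, set_b_size - k))
    return acc / total


class TestFisher:
    def test_hand_enumerated_overlap_example(self):
        universe = [f"g{i}" for i in range(10)]
        p = age_overlap_fisher({"g0", "g1", "g2"}, {"g1", "g2", "g3"},
                               universe)
        assert p == pytest.approx(22 / 120, abs=1e-12)

    def test_disjoint_sets_show_no_enrichment(self):
        universe = [f"g{i}" for i in range(6)]
        p = age_overlap_fisher({"g0", "g1", "g2"}, {"g3", "g4", "g5"},
                               universe)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        universe = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = set(rng.choice(universe, rng.integers(1, 7), replace=False))
            b = set(rng.choice(universe, rng.integers(1, 7), replace=False))
            p = age_overlap_fisher(a, b, universe)
            expected = _hypergeom_tail(len(a & b), len(a), len(b), 12)
            assert p == pytest.approx(expected, rel=1e-9)

    def test_geneset_enrichment_example(self):
        universe = [f"g{i}" for i in range(10)]
        cluster = ["g0", "g1", "g2", "g3"]
        gene_set = ["g0", "g1", "g2", "g3", "g4"]
        p, cluster_ratio, universe_ratio = geneset_enrichment(
            cluster, gene_set, universe)
        assert p == pytest.approx(5 / 210, abs=1e-12)
        assert cluster_ratio == pytest.approx(1.0)
        assert universe_ratio == pytest.approx(0.5)

    def test_geneset_disjoint_from_cluster(self):
        universe = [f"g{i}" for i in range(10)]
        p, ratio, _ = geneset_enrichment(["g0", "g1"], ["g8", "g9"], universe)
        assert p == pytest.approx(1.0)
        assert ratio == 0.0


class TestPipeline:
    def test_planted_recovery_single_seed(self):
        study, truth = gen_expression(ExprSimConfig(seed=3))
        table, model = deg_pipeline(study, seed=3)
        deg = table["is_deg"].reindex(truth.index, fill_value=False)
        recall = (deg & truth.is_deg).sum() / truth.is_deg.sum()
        fdr = (deg & ~truth.is_deg).sum() / max(int(deg.sum()), 1)
        assert recall >= 0.8
        assert fdr <= 0.1
        assert model.k == 3
        common = table.index[table.is_deg].intersection(
            truth.index[truth.cluster > 0])
        ari = adjusted_rand_score(truth.loc[common, "cluster"],
                                  table.loc[common, "cluster"])
        assert ari >= 0.8
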