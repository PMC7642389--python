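"""Differential expression: FPKM arithmetic, NB test behavior, DEG filtering."""

import numpy as np
import pandas as pd
import pytest

from regulonscope.config import RunConfig
from regulonscope.diffexpr import (
    ExpressionMatrix,
    cluster_degs,
    compute_fpkm,
    filter_degs,
    median_of_ratios_size_factors,
    summarize_degs,
)
from regulonscope.diffexpr import test_differential as nb_lrt


def make_matrix(counts: dict[str, list[int]], lengths: dict[str, int]) -> ExpressionMatrix:
    df = pd.DataFrame(counts).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    meta = pd.DataFrame({"sample": df.columns, "strain": "WT", "media": "plain",
                         "replicate": range(1, df.shape[1] + 1)})
    return ExpressionMatrix(counts=df, gene_lengths=pd.Series(lengths), samples=meta)


class TestComputeFpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s": [100]}, index=["g"])
        fpkm = compute_fpkm(counts, pd.Series({"g": 1000}), pd.Series({"s": 1e6}))
        assert fpkm.loc["g", "s"] == 100.0

    def test_length_and_depth_scaling(self):
        counts = pd.DataFrame({"s": [100]}, index=["g"])
        fpkm = compute_fpkm(counts, pd.Series({"g": 2000}), pd.Series({"s": 2e6}))
        assert fpkm.loc["g", "s"] == 25.0

    def test_zero_counts_give_zero(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        fpkm = compute_fpkm(counts, pd.Series({"g": 500}), pd.Series({"s": 1e6}))
        assert fpkm.loc["g", "s"] == 0.0

    def test_zero_length_gene_errors(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        with pytest.raises(ValueError, match="zero-length"):
            compute_fpkm(counts, pd.Series({"g": 0}), pd.Series({"s": 1e6}))

    def test_doubling_counts_and_library_leaves_fpkm_unchanged(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (10, 3)), columns=list("abc"))
        lengths = pd.Series(rng.integers(500, 2000, 10), index=counts.index)
        f1 = compute_fpkm(counts, lengths)
        f2 = compute_fpkm(counts * 2, lengths)
        assert np.allclose(f1.values, f2.values)


class TestTestDifferential:
    def test_identical_groups_null(self):
        m = make_matrix(
            {"g1": [100, 110, 100, 110], "g2": [50, 55, 50, 55]},
            {"g1": 1000, "g2": 1000},
        )
        res = nb_lrt(m, ["s0", "s1"], ["s2", "s3"])
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["p_value"] > 0.95).all()
        assert not res["significant"].any()

    def test_fourfold_fpkm_gives_log2fc_two(self):
        # identical library sizes, one gene 4x the other group's counts
        m = make_matrix(
            {"g1": [100, 100, 400, 400], "g2": [1000, 1000, 700, 700]},
            {"g1": 1000, "g2": 1000},
        )
        cfg = RunConfig(pseudo_fpkm=1e-9)
        res = nb_lrt(m, ["s0", "s1"], ["s2", "s3"], cfg).set_index("gene_id")
        assert res.loc["g1", "log2fc"] == pytest.approx(2.0, abs=0.05)

    def test_overlapping_groups_error(self):
        m = make_matrix({"g": [1, 2, 3, 4]}, {"g": 1000})
        with pytest.raises(ValueError, match="overlap"):
            nb_lrt(m, ["s0", "s1"], ["s1", "s2"])

    def test_single_replicate_error(self):
        m = make_matrix({"g": [1, 2, 3, 4]}, {"g": 1000})
        with pytest.raises(ValueError, match="replicates"):
            nb_lrt(m, ["s0"], ["s1", "s2"])

    def test_swapping_groups_negates_log2fc(self):
        rng = np.random.default_rng(5)
        counts = {f"g{i}": list(rng.poisson(200, 4)) for i in range(20)}
        m = make_matrix(counts, {f"g{i}": 1000 for i in range(20)})
        ab = nb_lrt(m, ["s0", "s1"], ["s2", "s3"])
        ba = nb_lrt(m, ["s2", "s3"], ["s0", "s1"])
        assert np.allclose(ab["log2fc"].values, -ba["log2fc"].values, atol=1e-9)
        assert np.allclose(ab["p_value"].values, ba["p_value"].values, atol=1e-9)

    def test_size_factors_resist_composition_bias(self):
        rng = np.random.default_rng(6)
        base = rng.poisson(1000, 30).astype(float)
        counts = {}
        for i, b in enumerate(base):
            fold = 10.0 if i < 5 else 1.0  # five genes 10x up in group B
            counts[f"g{i}"] = list(rng.poisson(b, 2)) + list(rng.poisson(b * fold, 2))
        m = make_matrix(counts, {f"g{i}": 1000 for i in range(30)})
        res = nb_lrt(m, ["s0", "s1"], ["s2", "s3"]).set_index("gene_id")
        null_lfc = res.loc[[f"g{i}" for i in range(5, 30)], "log2fc"]
        assert null_lfc.abs().mean() < 0.2

    def test_size_factor_helper_mean_one(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.poisson(100, (50, 4)), columns=list("abcd"))
        sf = median_of_ratios_size_factors(counts)
        assert sf.mean() == pytest.approx(1.0)


class TestFilterDegs:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "mean_fpkm_A", "mean_fpkm_B", "log2fc", "p_value",
                           "significant"],
        )

    def test_strict_inequalities(self):
        res = self._frame([
            ("boundary_lfc", 1, 2, 1.0, 0.01, False),   # excluded: strict >
            ("down", 4, 1, -1.2, 0.04, True),           # included, sign kept
            ("high_p", 1, 6, 2.5, 0.06, False),         # excluded: p not < 0.05
            ("clear_up", 1, 8, 3.0, 0.001, True),
        ])
        kept = filter_degs(res, RunConfig())
        assert list(kept["gene_id"]) == ["down", "clear_up"]
        assert (kept.set_index("gene_id").loc["down", "log2fc"]) == -1.2

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(8)
        res = self._frame([
            (f"g{i}", 1, 4, 2.0, p, False) for i, p in enumerate(rng.uniform(0, 0.2, 40))
        ])
        raw = filter_degs(res)
        adj = filter_degs(res, bh_correct=True)
        assert len(adj) <= len(raw)


class TestSummarizeDegs:
    def _sig(self, n_up, n_down):
        rows = [("u%d" % i, 1, 4, 2.0, 0.01, True) for i in range(n_up)]
        rows += [("d%d" % i, 4, 1, -2.0, 0.01, True) for i in range(n_down)]
        return pd.DataFrame(
            rows, columns=["gene_id", "mean_fpkm_A", "mean_fpkm_B", "log2fc", "p_value",
                           "significant"],
        )

    def test_percentages_to_one_decimal(self):
        s = summarize_degs(self._sig(274, 402), total_genes=5195)
        assert s["n_total"] == 676
        assert s["pct_total"] == 13.0
        assert s["pct_up"] == 5.3

    def test_counts_add_up(self):
        s = summarize_degs(self._sig(215, 227), total_genes=5195)
        assert s["n_total"] == s["n_up"] + s["n_down"]
        assert (s["pct_up"], s["pct_down"]) == (4.1, 4.4)

    def test_empty_is_zero(self):
        s = summarize_degs(self._sig(0, 0), total_genes=100)
        assert s["pct_total"] == 0.0

    def test_total_smaller_than_degs_errors(self):
        with pytest.raises(ValueError):
            summarize_degs(self._sig(5, 5), total_genes=3)


class TestClusterDegs:
    def test_identical_rows_merge_first(self):
        fpkm = pd.DataFrame(
            {
                "s1": [10.0, 10.0, 100.0],
                "s2": [20.0, 20.0, 50.0],
                "s3": [40.0, 40.0, 25.0],
            },
            index=["a", "b", "c"],
        )
        order, link = cluster_degs(fpkm, ["a", "b", "c"])
        # first merge joins the two identical rows at distance ~0
        first = set(link[0, :2].astype(int))
        assert first == {0, 1}
        assert link[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelated_rows_merge_last(self):
        fpkm = pd.DataFrame(
            {
                "s1": [10.0, 10.5, 100.0],
                "s2": [20.0, 21.0, 50.0],
                "s3": [40.0, 39.0, 25.0],
            },
            index=["up1", "up2", "down"],
        )
        _order, link = cluster_degs(fpkm, ["up1", "up2", "down"])
        # the final merge is at distance near 2 (perfect anticorrelation)
        assert link[-1, 2] > 1.5

    def test_strain_vs_media_clusters_recover_truth(self):
        rng = np.random.default_rng(9)
        n_each = 15
        samples = ["WT_p", "WT_a", "dTF_p", "dTF_a"]
        rows, labels = [], []
        for i in range(n_each):  # strain-responsive
            base = rng.uniform(20, 200)
            rows.append([base, base, base * 8, base * 8] * 1)
            labels.append(0)
        for i in range(n_each):  # media-responsive
            base = rng.uniform(20, 200)
            rows.append([base, base * 8, base, base * 8])
            labels.append(1)
        noise = rng.lognormal(0, 0.05, (2 * n_each, 4))
        fpkm = pd.DataFrame(np.array(rows) * noise, columns=samples,
                            index=[f"g{i}" for i in range(2 * n_each)])
        _order, link = cluster_degs(fpkm, list(fpkm.index))
        from scipy.cluster.hierarchy import fcluster
        from sklearn.metrics import adjusted_rand_score

        pred = fcluster(link, t=2, criterion="maxclust")
        assert adjusted_rand_score(labels, pred) >= 0.9

    def test_fewer_than_two_genes_errors(self):
        fpkm = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            cluster_degs(fpkm, ["g"])
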