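"""Marker detection (Wilcoxon + fold + Bonferroni) and cell typing."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import nephrokit as nk
from nephrokit.errors import ValidationError
from nephrokit.markers import rank_sum_p, rank_sum_p_exact


def _labels(cells, clusters, organoid="org1"):
    return pd.DataFrame({"cell": cells, "cluster": clusters, "organoid": [organoid] * len(cells)})


class TestRankSum:
    def test_extreme_three_vs_three_is_point_one(self):
        p = rank_sum_p_exact(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        p = rank_sum_p_exact(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(2, 9) for n2 in range(2, 9)])
    def test_exact_path_matches_scipy_for_all_small_sizes(self, n1, n2):
        """Tie-free data: enumeration equals scipy's exact distribution."""
        rng = np.random.default_rng(n1 * 100 + n2)
        x = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        a, b = x[:n1], x[n1:]
        ours = rank_sum_p_exact(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_path_matches_permutation_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 7, 2)
        a = rng.integers(0, 3, n1).astype(float)
        b = rng.integers(0, 3, n2).astype(float)

        def stat(x, y):
            r = scipy.stats.rankdata(np.concatenate([x, y]))
            return r[: len(x)].sum()

        ref = scipy.stats.permutation_test(
            (a, b), stat, permutation_type="independent", n_resamples=np.inf, alternative="two-sided"
        ).pvalue
        assert rank_sum_p_exact(a, b) == pytest.approx(ref, abs=1e-9)

    def test_dispatch_uses_asymptotic_for_large_groups(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert rank_sum_p(a, b) == pytest.approx(ref)


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert nk.bonferroni(0.001, 100) == pytest.approx(0.1)
        assert nk.bonferroni(0.5, 100) == 1.0
        assert nk.bonferroni(0.123, 1) == pytest.approx(0.123)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            nk.bonferroni(1.5, 10)


class TestWilcoxonMarkers:
    def _toy(self):
        """12 cells, 2 clusters; gene up elevated in cluster A."""
        rng = np.random.default_rng(0)
        base = rng.uniform(1.0, 2.0, size=(3, 12))
        base[0, :6] += 3.0  # gene 'up' high in first 6 cells
        norm = pd.DataFrame(base, index=["up", "flat1", "flat2"], columns=[f"c{i}" for i in range(12)])
        labels = _labels(norm.columns, ["A"] * 6 + ["B"] * 6)
        return norm, labels

    def test_planted_marker_found_with_direction(self):
        norm, labels = self._toy()
        res = nk.wilcoxon_markers(norm, labels)
        up = res[(res["cluster"] == "A") & (res["gene"] == "up")]
        assert len(up) == 1 and up.iloc[0]["direction"] == "up"
        down = res[(res["cluster"] == "B") & (res["gene"] == "up")]
        assert len(down) == 1 and down.iloc[0]["direction"] == "down"

    def test_cell_order_invariance(self):
        norm, labels = self._toy()
        perm = np.random.default_rng(3).permutation(norm.shape[1])
        res1 = nk.wilcoxon_markers(norm, labels)
        res2 = nk.wilcoxon_markers(norm.iloc[:, perm], labels)
        key = ["organoid", "cluster", "gene"]
        m = res1.set_index(key).sort_index().join(res2.set_index(key).sort_index(), rsuffix="_p")
        assert m["p_value"].to_numpy() == pytest.approx(m["p_value_p"].to_numpy())
        assert m["fold_change"].to_numpy() == pytest.approx(m["fold_change_p"].to_numpy())

    def test_rank_only_property_monotone_transform(self):
        """p-values depend on the expression values only through ranks."""
        norm, labels = self._toy()
        res1 = nk.wilcoxon_markers(norm, labels, fold_cutoff=1.0000001)
        res2 = nk.wilcoxon_markers(norm * 3.0, labels, fold_cutoff=1.0000001)  # monotone, rank-preserving
        key = ["organoid", "cluster", "gene"]
        j = res1.set_index(key).join(res2.set_index(key), rsuffix="_t", how="inner")
        assert len(j) > 0
        assert j["p_value"].to_numpy() == pytest.approx(j["p_value_t"].to_numpy())

    def test_significant_set_monotone_in_alpha_and_fold(self, sc_data):
        truth, norm = sc_data["truth"], sc_data["norm"]
        labels = _labels(norm.columns, truth.cluster.loc[norm.columns])
        base = nk.wilcoxon_markers(norm, labels, fold_cutoff=1.8, alpha=0.05)
        stricter_alpha = nk.wilcoxon_markers(norm, labels, fold_cutoff=1.8, alpha=0.01)
        stricter_fold = nk.wilcoxon_markers(norm, labels, fold_cutoff=2.5, alpha=0.05)
        s0 = set(map(tuple, base.loc[base.significant, ["cluster", "gene"]].to_numpy()))
        s1 = set(map(tuple, stricter_alpha.loc[stricter_alpha.significant, ["cluster", "gene"]].to_numpy()))
        s2 = set(map(tuple, stricter_fold.loc[stricter_fold.significant, ["cluster", "gene"]].to_numpy()))
        assert s1 <= s0 and s2 <= s0

    def test_small_cluster_skipped_with_warning(self):
        norm = pd.DataFrame(np.ones((2, 5)), index=["a", "b"], columns=[f"c{i}" for i in range(5)])
        labels = _labels(norm.columns, ["A"] + ["B"] * 4)
        with pytest.warns(UserWarning):
            res = nk.wilcoxon_markers(norm, labels)
        assert not (res["cluster"] == "A").any()

    def test_de_within_organoid_only(self):
        """Clusters are compared against other cells of the same organoid."""
        rng = np.random.default_rng(1)
        norm = pd.DataFrame(rng.uniform(1, 2, (2, 8)), index=["g1", "g2"], columns=[f"c{i}" for i in range(8)])
        labels = pd.DataFrame(
            {
                "cell": norm.columns,
                "cluster": ["A", "A", "B", "B", "A", "A", "B", "B"],
                "organoid": ["o1"] * 4 + ["o2"] * 4,
            }
        )
        res = nk.wilcoxon_markers(norm, labels, fold_cutoff=1.0000001)
        assert set(res["organoid"]) <= {"o1", "o2"}
        # each comparison uses 2 vs 2 cells: exact path, p from 4-choose-2 = 6 subsets
        assert (res["p_value"] >= 1 / 6 - 1e-12).all()

    def test_planted_markers_recovered(self, sc_data):
        truth, norm = sc_data["truth"], sc_data["norm"]
        labels = _labels(norm.columns, truth.cluster.loc[norm.columns])
        res = nk.wilcoxon_markers(norm, labels)
        sig = res[res["significant"]]
        found = set(zip(sig["cluster"], sig["gene"]))
        planted = {(c, g) for c, gs in truth.cluster_markers.items() for g in gs if g in norm.index}
        sensitivity = len(planted & found) / len(planted)
        assert sensitivity >= 0.9


class TestAssignCellTypes:
    def _ref(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        ref = pd.DataFrame(
            {"epithelial": rng.uniform(0, 5, 30), "stromal": rng.uniform(0, 5, 30)}, index=genes
        )
        return ref

    def test_cell_equal_to_reference_column_gets_that_label(self):
        ref = self._ref()
        norm = pd.DataFrame({"c1": ref["stromal"], "c2": ref["epithelial"]})
        labels = _labels(["c1", "c2"], ["k1", "k2"])
        per_cell, per_cluster = nk.assign_cell_types(norm, labels, ref)
        assert per_cell.set_index("cell").loc["c1", "cell_type"] == "stromal"
        assert per_cell.set_index("cell").loc["c2", "cell_type"] == "epithelial"

    def test_majority_vote_and_alphabetical_tie(self):
        ref = self._ref()
        cols = {f"c{i}": ref["epithelial"] + np.random.default_rng(i).normal(0, 0.01, 30) for i in range(3)}
        cols.update({f"d{i}": ref["stromal"] + np.random.default_rng(10 + i).normal(0, 0.01, 30) for i in range(2)})
        norm = pd.DataFrame(cols)
        labels = _labels(list(norm.columns), ["k"] * 5)
        _, per_cluster = nk.assign_cell_types(norm, labels, ref)
        assert per_cluster.iloc[0]["cell_type"] == "epithelial"  # 3-2 vote
        # 2-2 tie -> alphabetical winner
        norm_tie = norm[["c0", "c1", "d0", "d1"]]
        _, per_cluster_tie = nk.assign_cell_types(norm_tie, _labels(list(norm_tie.columns), ["k"] * 4), ref)
        assert per_cluster_tie.iloc[0]["cell_type"] == "epithelial"

    def test_too_few_shared_genes_rejected(self):
        ref = self._ref().iloc[:5]
        norm = pd.DataFrame({"c1": ref.iloc[:, 0]})
        with pytest.raises(ValidationError):
            nk.assign_cell_types(norm, _labels(["c1"], ["k"]), ref)

    def test_zero_noise_assignment_is_perfect(self):
        ref = self._ref()
        rng = np.random.default_rng(9)
        picks = rng.choice(ref.columns, size=20)
        norm = pd.DataFrame({f"c{i}": ref[t] for i, t in enumerate(picks)})
        per_cell, _ = nk.assign_cell_types(norm, _labels(list(norm.columns), ["k"] * 20), ref)
        assert list(per_cell["cell_type"]) == list(picks)
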