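"""Single-cell QC, normalization, cycle scoring, cutoffs and blacklists."""

import itertools

import numpy as np
import pandas as pd
import pytest

import nephrokit as nk
from nephrokit.errors import ConfigurationError, ValidationError
from nephrokit.scqc import Blacklists


def _cm(counts, mito=None, ids=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    ids = ids or [f"g{i}" for i in range(n)]
    genes = pd.DataFrame(
        {"symbol": ids, "chromosome": ["1"] * n, "is_mito": mito or [False] * n},
        index=pd.Index(ids, name="gene"),
    )
    return nk.CountMatrix(genes, [f"c{j}" for j in range(counts.shape[1])], counts)


class TestComputeQC:
    def test_mito_fraction_rule(self):
        # one cell with 45/100 mito transcripts: 0.45 > 0.40 -> excluded
        cm = _cm([[55], [45]], mito=[False, True])
        report, filtered = nk.compute_qc(cm, min_transcripts=10)
        assert report.loc[0, "mito_fraction"] == pytest.approx(0.45)
        assert bool(report.loc[0, "fail_mito"])
        assert filtered.n_cells == 0

    def test_transcript_total_rule_boundaries(self):
        # totals computed after mito removal; 999 < 1000 fails, 1000 passes
        cm = _cm([[999, 1000], [0, 0]], mito=[False, True])
        report, filtered = nk.compute_qc(cm)
        assert bool(report.loc[0, "fail_min_transcripts"])
        assert not bool(report.loc[1, "fail_min_transcripts"])
        assert filtered.cells == ["c1"]

    def test_mito_boundary_exactly_040_passes(self):
        cm = _cm([[600], [400]], mito=[False, True])
        report, _ = nk.compute_qc(cm, min_transcripts=100)
        assert report.loc[0, "mito_fraction"] == pytest.approx(0.40)
        assert bool(report.loc[0, "pass"])

    def test_six_cell_toy_matches_enumeration(self):
        """Surviving set equals an exhaustive per-cell rule evaluation."""
        totals = [999, 1000, 1500, 2000, 500, 3000]
        mito_fr = [0.0, 0.39, 0.41, 0.40, 0.10, 0.55]
        counts = np.zeros((2, 6), dtype=int)
        for j, (t, f) in enumerate(zip(totals, mito_fr)):
            m = int(round(t * f / (1 - f)))
            counts[0, j], counts[1, j] = t, m
        cm = _cm(counts, mito=[False, True])
        report, filtered = nk.compute_qc(cm)
        expected = {
            f"c{j}" for j, (t, f) in enumerate(zip(totals, mito_fr))
            if not (round(f, 10) > 0.40) and t >= 1000
        }
        assert set(filtered.cells) == expected

    def test_mito_genes_removed_from_output(self, toy_counts):
        _, filtered = nk.compute_qc(toy_counts, min_transcripts=1)
        assert not filtered.genes["is_mito"].any()

    def test_order_stability_under_cell_permutation(self, sc_data):
        cm = sc_data["cm"]
        rng = np.random.default_rng(1)
        perm = rng.permutation(cm.n_cells)
        shuffled = nk.CountMatrix(cm.genes.copy(), [cm.cells[i] for i in perm], cm.counts[:, perm])
        r1, _ = nk.compute_qc(cm)
        r2, _ = nk.compute_qc(shuffled)
        merged = r1.set_index("cell").join(r2.set_index("cell"), rsuffix="_p")
        assert (merged["pass"] == merged["pass_p"]).all()
        assert merged["mito_fraction"].to_numpy() == pytest.approx(merged["mito_fraction_p"].to_numpy())

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            nk.compute_qc(_cm(np.zeros((0, 0), dtype=int)))


class TestFilterGenes:
    @pytest.mark.parametrize(
        "cells_counts, kept",
        [
            ([2, 2, 1, 1, 1], True),  # 5 expressing, 2 with >=2
            ([5, 5, 5, 5], False),  # only 4 expressing cells
            ([1, 1, 1, 1, 1, 1], False),  # no cell with >=2
            ([2, 1, 1, 1, 1], False),  # only 1 cell with >=2
        ],
    )
    def test_rule_evaluation(self, cells_counts, kept):
        row = cells_counts + [0] * (8 - len(cells_counts))
        counts = np.vstack([row, np.full(8, 5)])  # companion gene always kept
        report, filtered = nk.filter_genes(_cm(counts))
        assert bool(report.loc["g0", "keep"]) is kept

    def test_boundary_enumeration(self):
        """All boundary combinations around (5 expressing, 2 with >=2)."""
        for n_expr, n_ge2 in itertools.product([4, 5, 6], [1, 2, 3]):
            if n_ge2 > n_expr:
                continue
            row = [2] * n_ge2 + [1] * (n_expr - n_ge2) + [0] * (10 - n_expr)
            report, _ = nk.filter_genes(_cm(np.vstack([row, np.full(10, 3)])))
            assert bool(report.loc["g0", "keep"]) is (n_expr >= 5 and n_ge2 >= 2)


class TestLognormalize:
    def test_hand_value(self):
        # cell total 100, gene count 10, scale 10000 -> ln(1 + 1000)
        cm = _cm([[10], [90]])
        norm = nk.lognormalize(cm)
        assert norm.iloc[0, 0] == pytest.approx(np.log(1001), abs=1e-4)
        assert norm.iloc[0, 0] == pytest.approx(6.9088, abs=1e-3)

    def test_zeros_preserved_and_scale_invariance(self):
        cm = _cm([[0, 3], [5, 7]])
        cm2 = _cm([[0, 6], [10, 14]])
        n1, n2 = nk.lognormalize(cm), nk.lognormalize(cm2)
        assert n1.iloc[0, 0] == 0.0
        np.testing.assert_allclose(n1.to_numpy(), n2.to_numpy())

    def test_rank_order_preserved_within_cell(self, sc_data):
        norm = sc_data["norm"]
        cm = sc_data["cm"]
        col = norm.columns[0]
        raw = pd.Series(cm.counts[:, cm.cells.index(col)], index=cm.genes.index).reindex(norm.index)
        x, y = raw.to_numpy(), norm[col].to_numpy()
        order = np.argsort(x)
        assert np.all(np.diff(y[order]) >= -1e-12)


class TestCycleScore:
    def test_elevated_markers_score_positive(self, sc_data):
        truth, norm = sc_data["truth"], sc_data["norm"]
        scores = nk.cycle_score(norm, truth.s_genes, truth.g2m_genes, seed=0)
        ph = truth.phase.loc[norm.columns]
        assert scores.loc[ph == "S", "s_score"].mean() > scores.loc[ph == "G1", "s_score"].mean()
        assert scores.loc[ph == "G2M", "g2m_score"].mean() > scores.loc[ph == "G1", "g2m_score"].mean()

    def test_symmetric_matrix_scores_near_zero(self):
        # every gene identical: markers indistinguishable from controls
        counts = np.tile(np.array([[5], [5], [5], [5]]), (1, 6))
        cm = _cm(counts)
        norm = nk.lognormalize(cm)
        scores = nk.cycle_score(norm, ["g0"], ["g1"], n_bins=2, n_ctrl=2, seed=0)
        assert scores.to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_all_markers_absent_rejected(self, sc_data):
        with pytest.raises(ValidationError):
            nk.cycle_score(sc_data["norm"], ["NOPE1"], ["NOPE2"], seed=0)

    def test_seed_determinism(self, sc_data):
        truth, norm = sc_data["truth"], sc_data["norm"]
        s1 = nk.cycle_score(norm, truth.s_genes, truth.g2m_genes, seed=5)
        s2 = nk.cycle_score(norm, truth.s_genes, truth.g2m_genes, seed=5)
        assert s1.equals(s2)


class TestGeneScoreCorrelations:
    def test_gene_equal_to_score_has_r_one(self):
        norm = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [1.0, 1.0, 1.0, 1.0]],
            index=["up", "down", "flat"],
            columns=list("abcd"),
        )
        scores = pd.DataFrame({"s_score": [1.0, 2.0, 3.0, 4.0], "g2m_score": [0.0, 1.0, 0.0, 1.0]}, index=list("abcd"))
        corr = nk.gene_score_correlations(norm, scores)
        assert corr.loc["up", "r_s"] == pytest.approx(1.0)
        assert corr.loc["down", "r_s"] == pytest.approx(-1.0)
        assert corr.loc["flat", "r_s"] == 0.0 and bool(corr.loc["flat", "constant"])

    def test_matches_hand_computed_pearson(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        s = np.array([2.0, 4.0, 4.0, 6.0])
        norm = pd.DataFrame([x], index=["g"], columns=list("abcd"))
        scores = pd.DataFrame({"s_score": s, "g2m_score": s[::-1]}, index=list("abcd"))
        corr = nk.gene_score_correlations(norm, scores)
        hand = np.corrcoef(x, s)[0, 1]
        assert corr.loc["g", "r_s"] == pytest.approx(hand, abs=1e-12)


class TestCycleCutoffs:
    def test_worked_example_type7_quantile(self):
        corr = pd.DataFrame(
            {
                "r_s": [0.5, 0.6, 0.7, 0.8, 0.1, 0.2, 0.3, 0.4],
                "r_g2m": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8],
            },
            index=[f"s{i}" for i in range(4)] + [f"g{i}" for i in range(4)],
        )
        cuts = nk.cycle_cutoffs(corr, [f"s{i}" for i in range(4)], [f"g{i}" for i in range(4)])
        # med(S_S)-med(S_G2M) = 0.65-0.25 = 0.40; Q25(S_S) type-7 = 0.575
        assert cuts.s_cut == pytest.approx(0.575, abs=1e-12)
        assert cuts.g2m_cut == pytest.approx(0.575, abs=1e-12)

    def test_constant_marker_sets(self):
        corr = pd.DataFrame(
            {"r_s": [0.8] * 3 + [0.2] * 3, "r_g2m": [0.2] * 3 + [0.8] * 3},
            index=["s0", "s1", "s2", "g0", "g1", "g2"],
        )
        cuts = nk.cycle_cutoffs(corr, ["s0", "s1", "s2"], ["g0", "g1", "g2"])
        assert cuts.s_cut == pytest.approx(max(0.6, 0.8))
        assert cuts.g2m_cut == pytest.approx(0.8)

    def test_identical_sets_reduce_to_quantile(self):
        vals = [0.3, 0.5, 0.7, 0.9]
        corr = pd.DataFrame({"r_s": vals, "r_g2m": vals}, index=list("wxyz"))
        cuts = nk.cycle_cutoffs(corr, list("wxyz"), list("wxyz"))
        assert cuts.s_cut == pytest.approx(np.quantile(vals, 0.25))

    def test_matches_sort_based_oracle_on_random_sets(self):
        """Independent sorting-based median/quantile implementation."""

        def q25_sorted(v):
            v = sorted(v)
            h = 0.25 * (len(v) - 1)
            lo = int(np.floor(h))
            return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])

        def med_sorted(v):
            v = sorted(v)
            n = len(v)
            return v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])

        rng = np.random.default_rng(42)
        for _ in range(200):
            n_s, n_g = rng.integers(1, 30, 2)
            s_names = [f"s{i}" for i in range(n_s)]
            g_names = [f"g{i}" for i in range(n_g)]
            corr = pd.DataFrame(
                {"r_s": rng.uniform(-1, 1, n_s + n_g), "r_g2m": rng.uniform(-1, 1, n_s + n_g)},
                index=s_names + g_names,
            )
            cuts = nk.cycle_cutoffs(corr, s_names, g_names)
            s_s = corr.loc[s_names, "r_s"].tolist()
            s_g = corr.loc[s_names, "r_g2m"].tolist()
            g_g = corr.loc[g_names, "r_g2m"].tolist()
            g_s = corr.loc[g_names, "r_s"].tolist()
            assert cuts.s_cut == pytest.approx(max(med_sorted(s_s) - med_sorted(s_g), q25_sorted(s_s)), abs=1e-12)
            assert cuts.g2m_cut == pytest.approx(max(med_sorted(g_g) - med_sorted(g_s), q25_sorted(g_g)), abs=1e-12)

    def test_empty_marker_set_rejected(self):
        corr = pd.DataFrame({"r_s": [0.5], "r_g2m": [0.5]}, index=["x"])
        with pytest.raises(ValidationError):
            nk.cycle_cutoffs(corr, ["absent"], ["x"])


class TestFlagCycleGenes:
    def test_boundary_is_strict(self):
        corr = pd.DataFrame({"r_s": [0.5, 0.500001], "r_g2m": [0.0, 0.0]}, index=["at", "above"])
        flags = nk.flag_cycle_genes(corr, nk.CutoffPair(0.5, 0.5))
        assert not bool(flags["at"])
        assert bool(flags["above"])

    def test_known_marker_flagged_even_below_cutoff(self):
        corr = pd.DataFrame({"r_s": [0.1], "r_g2m": [0.1]}, index=["mk"])
        flags = nk.flag_cycle_genes(corr, nk.CutoffPair(0.5, 0.5), known_markers=["mk"])
        assert bool(flags["mk"])

    def test_planted_cycle_genes_mostly_flagged(self, sc_data):
        truth, norm = sc_data["truth"], sc_data["norm"]
        scores = nk.cycle_score(norm, truth.s_genes, truth.g2m_genes, seed=0)
        corr = nk.gene_score_correlations(norm, scores)
        cuts = nk.cycle_cutoffs(corr, truth.s_genes, truth.g2m_genes)
        flags = nk.flag_cycle_genes(corr, cuts, truth.s_genes + truth.g2m_genes)
        extras = [g for g in truth.s_correlated + truth.g2m_correlated if g in flags.index]
        assert np.mean([flags[g] for g in extras]) >= 0.9


class TestBlacklist:
    def test_rp_prefix_removed_under_fig3(self):
        out = nk.blacklist_variable_genes(["RPL13A", "WT1"], [], Blacklists())
        assert out == ["WT1"]

    def test_chry_only_removed_under_early_late(self):
        ann = pd.DataFrame(
            {"symbol": ["UTY", "WT1"], "chromosome": ["Y", "11"]},
            index=pd.Index(["UTY", "WT1"], name="gene"),
        )
        keep_fig3 = nk.blacklist_variable_genes(["UTY", "WT1"], [], Blacklists(), "fig3", ann)
        keep_el = nk.blacklist_variable_genes(["UTY", "WT1"], [], Blacklists(), "early_late", ann)
        assert "UTY" in keep_fig3
        assert "UTY" not in keep_el

    def test_xist_tsix_and_lists_under_early_late(self):
        bl = Blacklists(heatshock=["HSPA1A"], ribosome=["RACK1"])
        genes = ["XIST", "TSIX", "HSPA1A", "RACK1", "WT1"]
        assert nk.blacklist_variable_genes(genes, [], bl, "early_late") == ["WT1"]

    def test_empty_blacklists_identity(self):
        genes = ["A1", "B2"]
        assert nk.blacklist_variable_genes(genes, [], Blacklists(sex_exclusive=[])) == genes

    def test_cycle_genes_removed(self):
        assert nk.blacklist_variable_genes(["A", "B"], ["B"], Blacklists()) == ["A"]

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            nk.blacklist_variable_genes(["A"], [], Blacklists(), profile="bogus")


class TestEndToEndQC:
    def test_planted_failures_are_exactly_the_excluded_set(self):
        from nephrokit.simulate import gen_sc_counts

        for seed in (0, 1, 2):
            cm, truth = gen_sc_counts(seed=seed)
            report, _ = nk.compute_qc(cm)
            failed = set(report.loc[~report["pass"], "cell"])
            assert failed == truth.expected_fail_cells
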