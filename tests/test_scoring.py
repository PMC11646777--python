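"""Unit and property tests for the four-method scoring and top-k union."""

import math

import numpy as np
import pandas as pd
import pytest

from kinscore import (
    METHODS,
    ScoringParams,
    ValidationError,
    compute_scores,
    flag_de,
    rank_by_method,
    select_top_union,
)

NAN = float("nan")


def naive_scores(stats, meta, params=ScoringParams()):
    """Independent double-loop recomputation of all four scores."""
    thr = math.log2(params.fc_threshold)
    genes = sorted(stats["gene_id"].unique())
    group_contrasts = {}
    for _, row in meta.iterrows():
        group_contrasts.setdefault(row["stress_group"], []).append(row["contrast_id"])
    lookup = {(r["gene_id"], r["contrast_id"]): (r["log2fc"], r["p_value"])
              for _, r in stats.iterrows()}
    out = {}
    for g in genes:
        T = TFC = AT = ATFC = 0.0
        for cons in group_contrasts.values():
            s = m = 0.0
            for c in cons:
                l2, p = lookup.get((g, c), (NAN, NAN))
                flagged = (not math.isnan(l2) and not math.isnan(p)
                           and p < params.p_threshold and abs(l2) >= thr)
                if flagged:
                    s += 1
                    m += abs(l2)
            T += s
            TFC += m
            AT += s / len(cons)
            ATFC += m / len(cons)
        out[g] = (T, TFC, AT, ATFC)
    return out


class TestFlagDe:
    @pytest.mark.parametrize("log2fc,p,expected", [
        (1.5, 0.01, True),      # exceeds both cuts
        (0.9, 0.001, False),    # below fold cut
        (-3.0, 0.049, True),    # down-regulation scores equally
        (4.0, NAN, False),      # missing p never flags
        (NAN, 0.01, False),     # missing fold change never flags
        (1.0, 0.01, True),      # boundary |log2fc| = 1 is inclusive
        (2.0, 0.05, False),     # p boundary is strict
    ])
    def test_examples(self, log2fc, p, expected):
        assert flag_de(log2fc, p) is expected

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            ScoringParams(fc_threshold=1.0)
        with pytest.raises(ValidationError):
            ScoringParams(p_threshold=0.0)
        with pytest.raises(ValidationError):
            ScoringParams(k=0)


class TestComputeScores:
    def test_hand_example(self, small_stats, small_meta):
        # flagged in 2/2 cold and 1/4 salt contrasts with |log2fc| 1.5, 2.5, 3.0
        sc = compute_scores(small_stats, small_meta)
        row = sc.loc["g1"]
        assert row["T"] == 3
        assert row["TFC"] == pytest.approx(7.0)
        assert row["AT"] == pytest.approx(2 / 2 + 1 / 4)
        assert row["ATFC"] == pytest.approx((1.5 + 2.5) / 2 + 3.0 / 4)

    def test_unflagged_gene_kept_with_zero_scores(self, small_meta):
        stats = pd.DataFrame({
            "gene_id": ["quiet"], "contrast_id": ["cold_c0"],
            "log2fc": [0.2], "p_value": [0.9],
        })
        sc = compute_scores(stats, small_meta)
        assert (sc.loc["quiet", ["T", "TFC", "AT", "ATFC"]] == 0).all()

    def test_contrast_missing_from_meta_is_error(self, small_stats, small_meta):
        bad = small_stats.copy()
        bad.loc[0, "contrast_id"] = "mystery_c9"
        with pytest.raises(ValidationError, match="mystery_c9"):
            compute_scores(bad, small_meta)

    def test_matches_naive_oracle_on_random_instance(self, random_study):
        stats, meta = random_study
        sc = compute_scores(stats, meta)
        expected = naive_scores(stats, meta)
        for g, (t, tfc, at, atfc) in expected.items():
            row = sc.loc[g]
            assert row["T"] == pytest.approx(t, abs=1e-12)
            assert row["TFC"] == pytest.approx(tfc, abs=1e-12)
            assert row["AT"] == pytest.approx(at, abs=1e-12)
            assert row["ATFC"] == pytest.approx(atfc, abs=1e-12)

    def test_total_equals_weighted_group_means(self, random_study):
        # T = sum_g n_g * (per-group mean indicator), exactly
        stats, meta = random_study
        sc = compute_scores(stats, meta)
        sizes = meta["stress_group"].value_counts()
        for g in ["g000", "g050", "g199"]:
            by_group = 0.0
            for grp, n_g in sizes.items():
                cons = meta.loc[meta["stress_group"] == grp, "contrast_id"]
                sub = stats[(stats["gene_id"] == g) & stats["contrast_id"].isin(cons)]
                flags = sum(flag_de(l, p) for l, p in zip(sub["log2fc"], sub["p_value"]))
                by_group += n_g * (flags / n_g)
            assert sc.loc[g, "T"] == pytest.approx(by_group, abs=1e-12)

    def test_fold_scores_bounded_below_by_count_scores(self, random_study):
        stats, meta = random_study
        sc = compute_scores(stats, meta)
        thr = math.log2(2.0)
        assert (sc["TFC"] >= sc["T"] * thr - 1e-12).all()
        assert (sc["ATFC"] >= sc["AT"] * thr - 1e-12).all()

    def test_group_duplication_leaves_averaged_scores_unchanged(self, random_study):
        # duplicating every cold contrast leaves AT/ATFC invariant but
        # strictly raises T/TFC for genes flagged in cold
        stats, meta = random_study
        base = compute_scores(stats, meta)

        cold = meta[meta["stress_group"] == "cold"]
        meta2 = pd.concat([meta, cold.assign(
            contrast_id=cold["contrast_id"] + "_dup")], ignore_index=True)
        dup_stats = stats[stats["contrast_id"].isin(cold["contrast_id"])].copy()
        dup_stats["contrast_id"] = dup_stats["contrast_id"] + "_dup"
        stats2 = pd.concat([stats, dup_stats], ignore_index=True)

        doubled = compute_scores(stats2, meta2)
        assert np.allclose(doubled["AT"], base["AT"], atol=1e-12)
        assert np.allclose(doubled["ATFC"], base["ATFC"], atol=1e-12)

        flagged_in_cold = doubled["T"] > base["T"]
        # exactly the genes flagged in a cold contrast gain score
        cold_cons = set(cold["contrast_id"])
        for g in base.index:
            sub = stats[(stats["gene_id"] == g) & stats["contrast_id"].isin(cold_cons)]
            had_cold_flag = any(flag_de(l, p) for l, p in
                                zip(sub["log2fc"], sub["p_value"]))
            assert flagged_in_cold[g] == had_cold_flag
            if had_cold_flag:
                assert doubled.loc[g, "TFC"] > base.loc[g, "TFC"]

    def test_row_order_never_matters(self, random_study):
        stats, meta = random_study
        shuffled = stats.sample(frac=1, random_state=3).reset_index(drop=True)
        meta_shuffled = meta.sample(frac=1, random_state=5).reset_index(drop=True)
        a = compute_scores(stats, meta)
        b = compute_scores(shuffled, meta_shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_adjusted_p_column_supported(self, small_meta):
        stats = pd.DataFrame({
            "gene_id": ["g1"], "contrast_id": ["cold_c0"],
            "log2fc": [2.0], "p_value": [0.01], "p_adj": [0.2],
        })
        raw = compute_scores(stats, small_meta)
        adj = compute_scores(stats, small_meta, ScoringParams(use_adjusted_p=True))
        assert raw.loc["g1", "T"] == 1 and adj.loc["g1", "T"] == 0


class TestRanking:
    def make_scores(self, t_values):
        df = pd.DataFrame({"T": t_values})
        df.index = pd.Index([f"{c}" for c in "abcdefghij"[:len(t_values)]],
                            name="gene_id")
        for m in ("TFC", "AT", "ATFC"):
            df[m] = df["T"].astype(float)
        return df

    def test_descending_with_lexicographic_ties(self):
        sc = self.make_scores([3, 5, 1])
        assert rank_by_method(sc, "T") == ["b", "a", "c"]
        sc = self.make_scores([2, 2])
        assert rank_by_method(sc, "T") == ["a", "b"]
        sc = self.make_scores([0, 0, 0])
        assert rank_by_method(sc, "T") == ["a", "b", "c"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            rank_by_method(self.make_scores([1]), "Z")


class TestSelection:
    def test_identical_rankings_give_union_of_k(self):
        n, k = 60, 30
        df = pd.DataFrame(
            {m: np.arange(n, 0, -1, dtype=float) for m in METHODS},
            index=pd.Index([f"g{i:02d}" for i in range(n)], name="gene_id"),
        )
        res = select_top_union(df, ScoringParams(k=k))
        assert len(res.union) == k
        assert (res.provenance["n_methods"] == 4).all()

    def test_disjoint_top_lists_give_union_of_4k(self):
        n, k = 120, 30
        genes = [f"g{i:03d}" for i in range(n)]
        df = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"),
                          columns=list(METHODS))
        for j, m in enumerate(METHODS):
            block = genes[j * k:(j + 1) * k]
            df.loc[block, m] = np.arange(k, 0, -1, dtype=float)
        res = select_top_union(df, ScoringParams(k=k))
        assert len(res.union) == 4 * k
        assert (res.provenance["n_methods"] == 1).all()

    def test_too_few_genes_is_error(self):
        df = pd.DataFrame({m: [1.0] for m in METHODS},
                          index=pd.Index(["g1"], name="gene_id"))
        with pytest.raises(ValidationError, match="only 1"):
            select_top_union(df, ScoringParams(k=30))

    def test_keep_all_extends_through_tie(self):
        # five genes tied at the k-th score: truncate keeps k, keep-all keeps all
        df = pd.DataFrame({m: [5.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0] for m in METHODS},
                          index=pd.Index(list("abcdefg"), name="gene_id"))
        trunc = select_top_union(df, ScoringParams(k=3))
        assert len(trunc.union) == 3
        keep = select_top_union(df, ScoringParams(k=3), ties="keep-all")
        assert len(keep.union) == 7

    def test_synthetic_broad_responders_all_selected(self):
        from kinscore import StudyDesign, simulate_study
        design = StudyDesign(seed=11)
        stats, meta, truth = simulate_study(design)
        scores = compute_scores(stats, meta)
        res = select_top_union(scores, ScoringParams(k=design.n_broad_responders))
        broad = set(truth.loc[truth["role"] == "broad", "gene_id"])
        assert broad <= set(res.union)
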