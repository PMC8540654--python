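import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal, mannwhitneyu

from phylloplane import (
    AsvTable,
    CommunitySimConfig,
    StudyDesign,
    aggregate_to_rank,
    find_indicators,
    kruskal_wallis_screen,
    lda_effect_size,
    remove_taxa_by_lineage,
    simulate_community,
)


class TestAggregateToRank:
    def test_single_genus_collapses_to_column_sums(self, toy_table):
        t = toy_table.subset_taxa(["t1", "t2"]).subset_samples(["s1", "s2"])
        t.taxonomy.loc[["t1", "t2"], "genus"] = "G"
        ra = aggregate_to_rank(t, "genus")
        assert list(ra.abundance.index) == ["G"]
        np.testing.assert_allclose(ra.abundance.loc["G"], 1e6)

    def test_per_million_arithmetic(self):
        counts = pd.DataFrame({"s": [30, 10]}, index=["a", "b"])
        tax = pd.DataFrame(
            {"kingdom": ["K", "K"], "genus": ["Ga", "Gb"]}, index=["a", "b"]
        )
        ra = aggregate_to_rank(AsvTable(counts, tax), "genus")
        assert ra.abundance.loc["Ga", "s"] == pytest.approx(750000)
        assert ra.abundance.loc["Gb", "s"] == pytest.approx(250000)

    def test_aggregation_commutes_with_totals(self, small_table):
        ra = aggregate_to_rank(small_table, "family")
        np.testing.assert_allclose(ra.abundance.sum(axis=0), 1e6, rtol=1e-9)
        raw_share = small_table.counts.groupby(
            small_table.taxonomy["family"]
        ).sum().div(small_table.counts.sum(axis=0), axis=1) * 1e6
        np.testing.assert_allclose(
            ra.abundance.sort_index().to_numpy(), raw_share.sort_index().to_numpy()
        )

    def test_unclassified_pooled_under_parent(self):
        counts = pd.DataFrame({"s": [3, 1]}, index=["a", "b"])
        tax = pd.DataFrame(
            {"family": ["F1", "F2"], "genus": ["G1", None]}, index=["a", "b"]
        )
        ra = aggregate_to_rank(AsvTable(counts, tax), "genus")
        assert "unclassified_F2" in ra.abundance.index

    def test_missing_rank_rejected(self, toy_table):
        with pytest.raises(ValueError):
            aggregate_to_rank(toy_table, "species")


class TestKruskalScreen:
    def _frame(self, rows: dict) -> pd.DataFrame:
        return pd.DataFrame(rows).T

    def test_matches_scipy_and_flags_below_alpha(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(size=(5, 24)) + 1000.0)
        groups = np.repeat(["a", "b", "c"], 8)
        out = kruskal_wallis_screen(values, groups)
        for taxon in values.index:
            x = values.loc[taxon].to_numpy()
            h, p = kruskal(*[x[groups == g] for g in ("a", "b", "c")])
            assert out.loc[taxon, "H"] == pytest.approx(h)
            assert out.loc[taxon, "p"] == pytest.approx(p)
            assert out.loc[taxon, "selected"] == (p < 0.05)

    def test_two_groups_reduce_to_rank_sum_test(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        groups = np.array(["a"] * 10 + ["b"] * 10)
        out = kruskal_wallis_screen(pd.DataFrame([x]), groups)
        p_ref = mannwhitneyu(
            x[:10], x[10:], method="asymptotic", use_continuity=False
        )[1]
        # KW with 2 groups equals the tie-corrected two-sided rank-sum test
        assert out.iloc[0]["p"] == pytest.approx(p_ref, rel=1e-6)

    def test_constant_taxon_excluded_with_note(self):
        values = pd.DataFrame([[5.0] * 12, list(range(12))])
        out = kruskal_wallis_screen(values, ["a"] * 6 + ["b"] * 6)
        assert out.iloc[0]["note"] == "constant"
        assert not out.iloc[0]["selected"]
        assert np.isnan(out.iloc[0]["p"])

    def test_null_selection_rate_near_alpha(self):
        rng = np.random.default_rng(9)
        hits = total = 0
        for _ in range(40):
            values = pd.DataFrame(rng.normal(size=(10, 30)))
            out = kruskal_wallis_screen(values, np.repeat(["a", "b", "c"], 10))
            hits += int(out["selected"].sum())
            total += len(out)
        rate = hits / total
        assert 0.01 < rate < 0.10  # ~alpha with Monte-Carlo slack

    def test_power_on_tenfold_shift(self):
        rng = np.random.default_rng(5)
        detected = 0
        for _ in range(40):
            base = rng.lognormal(np.log(200), 0.4, size=60)
            base[:20] *= 10.0
            out = kruskal_wallis_screen(
                pd.DataFrame([base]), np.repeat(["hi", "lo", "lo2"], 20)
            )
            detected += int(out.iloc[0]["selected"])
        assert detected >= 38  # >= 95% power


class TestLdaEffectSize:
    def test_empty_candidates_give_empty_table(self, small_table):
        ra = aggregate_to_rank(remove_taxa_by_lineage(small_table), "genus")
        labels = ["bcL"] * 24 + ["bcM"] * 24
        res = lda_effect_size(ra, labels, candidates=[], seed=0)
        assert res.table.empty and res.scores.empty

    def test_planted_indicator_recovered_with_its_category(self, small_community):
        counts, tax, meta, truth = small_community
        table = remove_taxa_by_lineage(AsvTable(counts, tax))
        res = find_indicators(table, meta["bc_category"], rank="genus", seed=3)
        planted = {
            tax.loc[t, "genus"]: cat for t, cat in truth.bc_indicator_taxa.items()
        }
        recovered = [g for g in planted if g in res.table.index]
        assert len(recovered) >= 0.8 * len(planted)
        for g in recovered:
            assert res.table.loc[g, "category"] == planted[g]

    def test_scores_below_threshold_filtered_but_retrievable(self, small_community):
        counts, tax, meta, _ = small_community
        table = remove_taxa_by_lineage(AsvTable(counts, tax))
        res = find_indicators(
            table, meta["bc_category"], rank="genus", seed=3, score_threshold=100.0
        )
        assert res.table.empty
        assert len(res.scores) > 0  # pre-filter scores retained

    def test_reported_rows_satisfy_both_thresholds(self, small_community):
        counts, tax, meta, _ = small_community
        table = remove_taxa_by_lineage(AsvTable(counts, tax))
        res = find_indicators(table, meta["bc_category"], rank="genus", seed=1)
        assert (res.table["lda_score"] >= 2.0).all()
        assert (res.table["p"] < 0.05).all()

    def test_effect_score_monotone_in_planted_fold_change(self):
        """A fixed taxon's score never decreases along a fold-change ladder."""
        design = StudyDesign(rounds=2)
        scores = []
        for mult in (1.5, 3.0, 6.0, 12.0, 24.0):
            cfg = CommunitySimConfig(
                n_taxa=40,
                bc_effect_taxa_fraction=0.075,  # 3 taxa, one per category
                bc_effect_multiplier={"bcL": mult, "bcM": mult, "bcH": mult},
                season_effect_taxa_fraction=0.0,
                chloroplast_taxa=0,
                seed=17,
            )
            counts, tax, meta, truth = simulate_community(design, cfg)
            taxon = next(t for t, c in truth.bc_indicator_taxa.items() if c == "bcH")
            ra = aggregate_to_rank(AsvTable(counts, tax), "genus")
            genus = tax.loc[taxon, "genus"]
            res = lda_effect_size(
                ra, meta["bc_category"].to_numpy(), [genus], seed=5, score_threshold=0.0
            )
            scores.append(res.scores.loc[genus, "lda_score"])
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_recovery_over_replicates(self):
        """Planted genus-rank indicators are recovered in >= 80% of cases
        with their planted enrichment category."""
        design = StudyDesign(rounds=2)
        recovered = planted_total = mislabelled = 0
        for rep in range(15):
            cfg = CommunitySimConfig(n_taxa=60, chloroplast_taxa=0, seed=100 + rep)
            counts, tax, meta, truth = simulate_community(design, cfg)
            table = AsvTable(counts, tax)
            res = find_indicators(table, meta["bc_category"], rank="genus", seed=rep)
            planted = {
                tax.loc[t, "genus"]: cat for t, cat in truth.bc_indicator_taxa.items()
            }
            found = set(res.table.index)
            for g, cat in planted.items():
                planted_total += 1
                if g in found:
                    recovered += 1
                    mislabelled += int(res.table.loc[g, "category"] != cat)
        assert recovered >= 0.8 * planted_total
        assert mislabelled == 0

    def test_null_community_reports_at_screen_level(self):
        """With no planted effects, the fraction of taxa reported is bounded
        by the raw-p Kruskal-Wallis screen level (alpha = 0.05) plus
        Monte-Carlo slack.  Exact zero is unreachable by construction: the
        screen uses unadjusted p-values, so ~alpha of null taxa pass it and
        most of those clear the per-million score threshold."""
        design = StudyDesign(rounds=2)
        reported = total = 0
        for rep in range(15):
            cfg = CommunitySimConfig(
                n_taxa=60,
                chloroplast_taxa=0,
                bc_effect_multiplier={"bcL": 1.0, "bcM": 1.0, "bcH": 1.0},
                season_effect_multiplier=1.0,
                seed=300 + rep,
            )
            counts, tax, meta, _ = simulate_community(design, cfg)
            res = find_indicators(
                AsvTable(counts, tax), meta["bc_category"], rank="genus", seed=rep
            )
            reported += len(res.table)
            total += cfg.n_taxa
        assert reported / total < 0.10
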