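"""Discovery filter, clumping, replication rule, FDR and novelty."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crosstrait.loci import (
    DiscoveryCriteria,
    Locus,
    PairwiseR2,
    ReplicationRecord,
    annotate_novelty,
    apply_discovery_filter,
    apply_replication_filter,
    bh_fdr,
    clump,
    collapse_cross_analysis,
    combine_disc_rep,
    evaluate_reported_table,
    one_sided_p,
)

from conftest import bh_oracle, greedy_clump_oracle


class TestDiscoveryFilter:
    @pytest.mark.parametrize(
        "p_biv,p1,p2,same_dir,expected_pass",
        [
            # printed lead variants: concordant, strongly significant
            (4.80e-12, 1.89e-4, 1.47e-9, True, True),
            (1.36e-8, 3.18e-5, 1.14e-5, True, True),
            # order-of-magnitude rule violated: 4e-8 > 3e-7/10
            (4e-8, 3e-7, 1e-9, True, False),
            # exact boundary is accepted (non-strict)
            (3e-8, 3e-7, 3e-7, True, True),
            # univariate nominal-significance rule
            (1e-12, 2e-3, 1e-9, True, False),
            # discordant directions
            (1e-12, 1e-5, 1e-5, False, False),
        ],
    )
    def test_four_criteria(self, p_biv, p1, p2, same_dir, expected_pass):
        passed, failed = apply_discovery_filter(
            {"p_biv": p_biv, "p1": p1, "p2": p2, "same_direction": same_dir}
        )
        assert passed is expected_pass
        assert (len(failed) == 0) is expected_pass

    def test_failed_criteria_enumerated(self):
        _, failed = apply_discovery_filter(
            {"p_biv": 1e-6, "p1": 0.5, "p2": 1e-9, "same_direction": False}
        )
        assert set(failed) == {"genome_wide", "magnitude", "uni_p1", "direction"}

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            DiscoveryCriteria(magnitude_factor=0.5)


def _passing_df(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p_biv"])


class TestClump:
    def test_single_snp_is_its_own_locus(self):
        loci = clump(_passing_df([("rs1", "1", 100, 1e-9)]), PairwiseR2())
        assert len(loci) == 1
        assert loci[0].lead == "rs1" and loci[0].members == {"rs1"}

    def test_high_ld_pair_merges(self):
        r2 = PairwiseR2([("rs4765914", "rs10774037", 0.99)])
        loci = clump(
            _passing_df([("rs4765914", "12", 2420377, 3.77e-9),
                         ("rs10774037", "12", 2420526, 6.40e-12)]),
            r2,
        )
        assert len(loci) == 1
        assert loci[0].lead == "rs10774037"  # smaller p leads

    def test_moderate_ld_pair_merges_above_threshold(self):
        r2 = PairwiseR2([("rs16836940", "rs2318763", 0.39)])
        loci = clump(
            _passing_df([("rs16836940", "1", 150416913, 1.28e-8),
                         ("rs2318763", "1", 150115974, 1.48e-11)]),
            r2,
        )
        assert len(loci) == 1

    def test_window_limits_absorption(self):
        r2 = PairwiseR2([("a", "b", 0.9)])
        loci = clump(
            _passing_df([("a", "1", 100, 1e-9), ("b", "1", 2_000_000, 1e-8)]),
            r2,
        )
        assert len(loci) == 2  # linked but outside the +-1 Mb window

    def test_absorption_not_chained(self):
        # b links to lead a; c links only to b -> c seeds its own locus
        r2 = PairwiseR2([("a", "b", 0.5), ("b", "c", 0.5)])
        loci = clump(
            _passing_df([("a", "1", 100, 1e-12), ("b", "1", 200, 1e-10),
                         ("c", "1", 300, 1e-8)]),
            r2,
        )
        assert {loc.lead for loc in loci} == {"a", "c"}
        assert next(l.members for l in loci if l.lead == "a") == {"a", "b"}

    def test_leads_pairwise_independent_and_partition(self):
        rng = np.random.default_rng(0)
        df, r2 = _random_instance(rng, n=40)
        loci = clump(df, r2)
        by_id = df.set_index("snp_id")
        leads = [loc.lead for loc in loci]
        # independence of leads holds within a chromosome and clump window
        for i in range(len(leads)):
            for j in range(i + 1, len(leads)):
                a, b = by_id.loc[leads[i]], by_id.loc[leads[j]]
                if a["chrom"] == b["chrom"] and abs(a["pos"] - b["pos"]) <= 1_000_000:
                    assert r2(leads[i], leads[j]) <= 0.10
        all_members = [s for loc in loci for s in loc.members]
        assert sorted(all_members) == sorted(df["snp_id"])
        for loc in loci:
            assert loc.p_lead == min(
                df.set_index("snp_id").loc[list(loc.members), "p_biv"]
            )

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            df, r2 = _random_instance(rng, n=int(rng.integers(2, 50)))
            ours = {(loc.lead, loc.members) for loc in clump(df, r2)}
            oracle = set(greedy_clump_oracle(df, r2))
            assert ours == oracle


def _random_instance(rng, n=30):
    """Random clumping instance: clustered positions, random sparse LD."""
    pos = np.sort(rng.integers(1, 3_000_000, n))
    df = pd.DataFrame(
        {
            "snp_id": [f"v{i}" for i in range(n)],
            "chrom": rng.choice(["1", "2"], n),
            "pos": pos,
            "p_biv": rng.uniform(1e-12, 1e-8, n),
        }
    )
    r2 = PairwiseR2()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.2:
                r2.set(f"v{i}", f"v{j}", float(rng.uniform(0, 1)))
    return df, r2


class TestOneSidedP:
    def test_examples(self):
        assert one_sided_p(0.0, +1) == pytest.approx(0.5)
        assert one_sided_p(1.6449, "+") == pytest.approx(0.05, abs=1e-4)
        assert one_sided_p(-1.6449, +1) == pytest.approx(0.95, abs=1e-4)
        assert one_sided_p(-1.6449, "-") == pytest.approx(0.05, abs=1e-4)

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            one_sided_p(1.0, 0)


class TestCombineDiscRep:
    def test_equal_n_equal_z(self):
        t, _ = combine_disc_rep(3.0, 3.0, 1e5, 1e5)
        assert t == pytest.approx(3.0 * np.sqrt(2), rel=1e-12)

    def test_vanishing_replication_limit(self):
        t, _ = combine_disc_rep(3.0, 10.0, 1e5, 1e-8)
        assert t == pytest.approx(3.0, abs=1e-4)

    def test_direct_formula(self):
        n_d, n_r = 377_371, 322_580
        t, p = combine_disc_rep(5.68, 2.59, n_d, n_r)
        expected = (np.sqrt(n_d) * 5.68 + np.sqrt(n_r) * 2.59) / np.sqrt(n_d + n_r)
        assert t == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(expected), rel=1e-10)


class TestReplicationFilter:
    @pytest.mark.parametrize(
        "p_rep,consistent,p_comb,p_disc,expected",
        [
            # nominally significant, consistent, combined more significant
            (3.66e-5, True, 1.52e-11, 5.25e-9, True),
            # combined p NOT more significant than discovery
            (4.48e-2, True, 4.70e-9, 3.40e-9, False),
            # replication p above 0.05
            (4.12e-1, True, 4.48e-9, 3.05e-10, False),
            # inconsistent direction
            (1e-3, False, 1e-12, 1e-9, False),
        ],
    )
    def test_three_criteria(self, p_rep, consistent, p_comb, p_disc, expected):
        rec = ReplicationRecord(
            snp_id="rs", p_rep_one_sided=p_rep, direction_consistent=consistent,
            p_combined=p_comb, p_biv_discovery=p_disc,
        )
        assert rec.replicated is expected
        assert apply_replication_filter(rec) is expected

    def test_missing_statistic_is_untested(self):
        rec = ReplicationRecord(
            snp_id="rs", p_rep_one_sided=None, direction_consistent=None,
            p_combined=None, p_biv_discovery=1e-9,
        )
        assert rec.untested and not rec.replicated


class TestCollapse:
    def _locus(self, lead, analysis="A", members=None):
        members = frozenset(members or [lead])
        return Locus(lead=lead, members=members, analysis=analysis)

    def test_shared_snp_merges(self):
        comps = collapse_cross_analysis(
            [self._locus("rs1", "BPD"), self._locus("rs1", "SCZ")], PairwiseR2()
        )
        assert len(comps) == 1

    def test_linked_leads_merge(self):
        r2 = PairwiseR2([("rs1", "rs2", 0.39)])
        comps = collapse_cross_analysis(
            [self._locus("rs1"), self._locus("rs2", "B")], r2
        )
        assert len(comps) == 1

    def test_disjoint_loci_counted(self):
        comps = collapse_cross_analysis(
            [self._locus(f"rs{i}") for i in range(5)], PairwiseR2()
        )
        assert len(comps) == 5


class TestBHFDR:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.01]), [0.01])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @given(
        st.lists(st.floats(1e-10, 1.0, allow_nan=False), min_size=1, max_size=8)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_textbook_oracle(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_oracle(pvals), atol=1e-12)


class TestNovelty:
    def _loci_df(self):
        return pd.DataFrame(
            {
                "lead": ["rs1", "rs2", "rs3"],
                "gene": ["FHIT", "MUC21", "PLEK2"],
                "replicated": [True, True, False],
            }
        )

    def test_prior_reported_not_novel(self, known_genes):
        novel = annotate_novelty(self._loci_df(), known_genes)
        assert list(novel) == [False, True, False]

    def test_empty_known_list_makes_all_replicated_novel(self):
        novel = annotate_novelty(self._loci_df(), set())
        assert list(novel) == [True, True, False]


class TestReportedTable:
    def test_row_order_invariance(self, reported_table, reported_ld, known_genes):
        base = evaluate_reported_table(reported_table, reported_ld, known_genes)
        shuffled = reported_table.sample(frac=1, random_state=3)
        again = evaluate_reported_table(shuffled, reported_ld, known_genes)
        assert (base.n_loci, base.n_replicated, base.n_novel) == (
            again.n_loci, again.n_replicated, again.n_novel
        )
        assert base.replicated_genes == again.replicated_genes

    def test_all_printed_rows_pass_discovery(self, reported_table, reported_ld,
                                             known_genes):
        s = evaluate_reported_table(reported_table, reported_ld, known_genes)
        assert s.per_row["discovery_pass"].all()

    def test_per_analysis_replication_counts(self, reported_table, reported_ld,
                                             known_genes):
        s = evaluate_reported_table(reported_table, reported_ld, known_genes)
        counts = s.per_row.groupby("analysis")["replication_pass"].sum().to_dict()
        assert counts == {"sMDD": 3, "rMDD": 0, "BPD": 1, "SCZ": 10}
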