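"""Odds ratios, Breslow-Day homogeneity, Holm step-down, and the screen."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sipscreen import (
    ConfigurationError,
    ContingencyPair,
    LabelScreen,
    OddsRatioPair,
    UndefinedStatisticError,
    ValidationError,
    aggregate_labelled_taxa,
    breslow_day,
    build_contingency,
    classify_label,
    holm_bonferroni,
    mh_common_odds_ratio,
    odds_ratio,
    run_labelling_screen,
    simulate_community,
    simulate_sip_experiment,
)
from sipscreen.io import SipCountTable, TaxonomyMap

from conftest import four_sample_meta, toy_experiment_table
from helpers import bd_statistic_oracle, holm_oracle, mh_or_oracle, random_corrected_strata


class TestOddsRatio:
    def test_symmetric_counts_give_unity(self):
        assert odds_ratio(10, 90, 10, 90) == 1.0

    def test_direct_evaluation(self):
        assert odds_ratio(20, 80, 10, 90) == pytest.approx((20 / 80) / (10 / 90))

    def test_haldane_zero_cell(self):
        expected = (0.5 / 100.5) / (10.5 / 90.5)
        assert odds_ratio(0, 100, 10, 90) == pytest.approx(expected)
        assert expected == pytest.approx(0.0429, abs=1e-4)

    def test_strict_policy_raises_on_zero(self):
        with pytest.raises(UndefinedStatisticError):
            odds_ratio(0, 100, 10, 90, correction="strict")

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            odds_ratio(0, 0, 0, 0)

    @given(
        cells=st.tuples(*[st.integers(1, 200)] * 4),
        k=st.integers(2, 20),
    )
    def test_scale_invariance_without_correction(self, cells, k):
        a, b, c, d = cells
        assert odds_ratio(a * k, b * k, c * k, d * k, correction="strict") == pytest.approx(
            odds_ratio(a, b, c, d, correction="strict")
        )


class TestMantelHaenszel:
    def test_identical_unit_or_strata(self):
        pair = ContingencyPair((10, 10, 10, 10), (10, 10, 10, 10))
        assert mh_common_odds_ratio(pair) == 1.0

    def test_hand_computed_sums(self):
        pair = ContingencyPair((30, 70, 10, 90), (10, 90, 10, 90))
        assert mh_common_odds_ratio(pair) == pytest.approx(
            mh_or_oracle([(30, 70, 10, 90), (10, 90, 10, 90)])
        )

    def test_single_informative_stratum_reduces_to_sample_or(self):
        # an incubation with no reads is excluded; the pooled OR collapses
        # to the remaining stratum's sample odds ratio
        pair = ContingencyPair((20, 80, 10, 90), (0, 0, 0, 0))
        assert mh_common_odds_ratio(pair) == pytest.approx(odds_ratio(20, 80, 10, 90))
        # and the homogeneity test is then undefined (df = 0)
        with pytest.raises(UndefinedStatisticError, match="strata"):
            breslow_day(pair)


class TestBreslowDay:
    def test_identical_strata_are_homogeneous(self):
        pair = ContingencyPair((10, 10, 10, 10), (10, 10, 10, 10))
        res = breslow_day(pair)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_statistic_matches_numeric_root_oracle(self):
        strata = [(10, 10, 10, 10), (30, 10, 10, 30)]
        pair = ContingencyPair(*strata)
        res = breslow_day(pair)
        assert res.statistic == pytest.approx(bd_statistic_oracle(strata), abs=1e-8)
        assert 0 <= res.p_value <= 1

    def test_closed_form_root_on_randomized_tables(self):
        rng = np.random.default_rng(20260923)
        for _ in range(100):
            strata = random_corrected_strata(rng)
            pair = ContingencyPair(*strata)
            res = breslow_day(pair)
            assert res.statistic == pytest.approx(
                bd_statistic_oracle(strata), abs=1e-8
            )
            for (a, b, c, d), a_fit in zip(strata, res.expected_a):
                n = a + b + c + d
                assert max(0.0, (a + b) + (a + c) - n) < a_fit < min(a + b, a + c)

    def test_matches_statsmodels_stratified_table(self):
        StratifiedTable = pytest.importorskip(
            "statsmodels.stats.contingency_tables"
        ).StratifiedTable
        rng = np.random.default_rng(7)
        for _ in range(25):
            cells = rng.integers(1, 51, size=8).astype(float)
            pair = ContingencyPair(tuple(cells[:4]), tuple(cells[4:]))
            tables = np.zeros((2, 2, 2))
            for k, s in enumerate([pair.c12, pair.c13]):
                tables[:, :, k] = [[s[0], s[1]], [s[2], s[3]]]
            st_tab = StratifiedTable(tables)
            assert breslow_day(pair).statistic == pytest.approx(
                st_tab.test_equal_odds(adjust=False).statistic
            )
            assert breslow_day(pair, tarone=True).statistic == pytest.approx(
                st_tab.test_equal_odds(adjust=True).statistic
            )
            assert mh_common_odds_ratio(pair) == pytest.approx(st_tab.oddsratio_pooled)

    def test_tarone_never_exceeds_plain_statistic(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            strata = random_corrected_strata(rng)
            pair = ContingencyPair(*strata)
            assert (
                breslow_day(pair, tarone=True).statistic
                <= breslow_day(pair).statistic + 1e-12
            )

    def test_degenerate_margins_raise_with_guidance(self):
        pair = ContingencyPair((0, 10, 0, 10), (5, 5, 5, 5))
        with pytest.raises(UndefinedStatisticError, match="correction"):
            breslow_day(pair, correction="strict")


class TestHolm:
    def test_worked_thresholds_all_rejected(self):
        dec = holm_bonferroni([0.01, 0.02, 0.04], alpha=0.05)
        assert [d.threshold for d in dec] == pytest.approx(
            [0.05 / 3, 0.05 / 2, 0.05 / 1]
        )
        assert all(d.reject for d in dec)

    def test_step_down_stops_at_first_failure(self):
        dec = holm_bonferroni([0.02, 0.5], alpha=0.05)
        assert [d.reject for d in dec] == [True, False]
        # a p below its own threshold is still blocked by an earlier failure
        dec = holm_bonferroni([0.026, 0.03], alpha=0.05)
        assert [d.reject for d in dec] == [False, False]

    def test_boundary_equality_not_rejected(self):
        dec = holm_bonferroni([0.05], alpha=0.05)
        assert not dec[0].reject

    def test_p_of_one_never_rejected(self):
        assert not any(d.reject for d in holm_bonferroni([1.0, 1.0], alpha=0.2))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            holm_bonferroni([0.5, 1.5])

    def test_empty_list_ok(self):
        assert holm_bonferroni([], alpha=0.05) == []

    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
        alpha=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_brute_force_and_nests_bonferroni(self, ps, alpha):
        dec = holm_bonferroni(ps, alpha=alpha)
        assert [d.reject for d in dec] == holm_oracle(ps, alpha)
        n = len(ps)
        for d in dec:
            if d.p_value < alpha / n:  # Bonferroni subset...
                pass  # may still be blocked only by an earlier failure, which
                # cannot happen: all earlier ps are <= this one < alpha/n
            if d.p_value < alpha / n:
                assert d.reject
            if d.reject:  # ...and contained in the unadjusted set
                assert d.p_value < alpha

    def test_agrees_with_statsmodels_multipletests(self):
        multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
        rng = np.random.default_rng(3)
        for _ in range(50):
            ps = rng.uniform(size=rng.integers(1, 30))
            mine = [d.reject for d in holm_bonferroni(ps, alpha=0.05)]
            ref = multipletests(ps, alpha=0.05, method="holm")[0].tolist()
            assert mine == ref


class TestClassify:
    @pytest.mark.parametrize(
        "or12,or13,sig,expected",
        [
            (1.0, 5.0, True, "labelled"),
            (5.0, 1.0, True, "unlabelled"),
            (1.0, 5.0, False, "none"),
            (2.0, 2.0, True, "none"),
        ],
    )
    def test_direction_rules(self, or12, or13, sig, expected):
        assert classify_label(OddsRatioPair(or12, or13), sig) == expected


class TestContingency:
    def test_counts_and_complements(self, toy_table):
        pair = build_contingency(toy_table, "Otu001")
        assert pair.c13 == (30.0, 70.0, 10.0, 90.0)
        assert pair.c12 == (10.0, 90.0, 10.0, 90.0)

    def test_absent_taxon_is_all_complement(self):
        table = toy_experiment_table()
        # Otu002 complements Otu001 exactly
        pair = build_contingency(table, "Otu002")
        assert pair.c13[0] + pair.c13[1] == 100
        assert pair.c13[0] == 70

    def test_missing_sample_names_the_gap(self, toy_table):
        meta = {k: v for k, v in four_sample_meta().items() if k != "C13_heavy"}
        broken = SipCountTable(
            otu_ids=toy_table.otu_ids,
            sample_ids=list(meta),
            counts=toy_table.counts[:, :3],
            meta=meta,
        )
        with pytest.raises(ConfigurationError, match="C13.*heavy"):
            build_contingency(broken, "Otu001")

    def test_unknown_taxon(self, toy_table):
        with pytest.raises(ValidationError):
            build_contingency(toy_table, "Otu999")


class TestScreen:
    def test_identical_isotope_samples_yield_nothing(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 100, size=(50, 2))
        counts = np.hstack([counts, counts])  # C13 duplicates C12 exactly
        table = SipCountTable(
            otu_ids=[f"Otu{i:03d}" for i in range(50)],
            sample_ids=["C12_light", "C12_heavy", "C13_light", "C13_heavy"],
            counts=counts,
            meta=four_sample_meta(),
        )
        calls = run_labelling_screen(table)
        assert all(c.direction == "none" for c in calls)
        assert all(not c.significant for c in calls)

    def test_empty_table_gives_empty_calls(self):
        table = SipCountTable(
            otu_ids=[],
            sample_ids=list(four_sample_meta()),
            counts=np.zeros((0, 4), dtype=int),
            meta=four_sample_meta(),
        )
        assert run_labelling_screen(table) == []

    def test_all_zero_taxa_skipped(self):
        counts = np.array([[5, 5, 5, 5], [0, 0, 0, 0]])
        table = SipCountTable(
            otu_ids=["OtuA", "OtuB"],
            sample_ids=list(four_sample_meta()),
            counts=counts,
            meta=four_sample_meta(),
        )
        calls = run_labelling_screen(table)
        assert [c.otu_id for c in calls] == ["OtuA"]

    def test_min_total_filters_family_size(self):
        counts = np.array([[50, 50, 50, 50], [1, 1, 1, 0]])
        table = SipCountTable(
            otu_ids=["OtuA", "OtuB"],
            sample_ids=list(four_sample_meta()),
            counts=counts,
            meta=four_sample_meta(),
        )
        calls = run_labelling_screen(table, min_total=10)
        assert len(calls) == 1 and calls[0].holm_threshold == pytest.approx(0.05)

    def test_simulated_truth_recovery(self):
        # 200 taxa, 5 strongly labelled, 50k reads: essentially full recovery
        recovered = []
        false_lab = []
        for seed in range(1, 21):
            prof = simulate_community(200, labelled_fraction=0.025, seed=seed)
            exp = simulate_sip_experiment(prof, seed=1000 + seed)
            res = LabelScreen(exp.table).fit()
            lab = {c.otu_id for c in res.labelled}
            truth = set(exp.truth[exp.truth].index)
            recovered.append(len(lab & truth))
            false_lab.append(len(lab - truth))
        assert np.mean(recovered) >= 4.0
        assert np.mean(false_lab) <= 0.5

    def test_step_down_consistency_invariant(self):
        prof = simulate_community(300, seed=9)
        exp = simulate_sip_experiment(prof, seed=99)
        calls = run_labelling_screen(exp.table)
        by_rank = sorted(calls, key=lambda c: c.holm_rank)
        seen_failure = False
        for c in by_rank:
            if c.significant:
                assert not seen_failure  # rejections form a prefix of the ranking
                assert c.p_raw < c.holm_threshold
            else:
                seen_failure = True


class TestModelInterface:
    def test_from_dataframe_and_summary(self, toy_table):
        res = LabelScreen.from_dataframe(toy_table.to_frame(), four_sample_meta()).fit()
        assert res.n_tested == 2
        text = res.summary()
        assert "taxa tested" in text and "2" in text
        frame = res.to_frame()
        assert list(frame.columns)[:2] == ["or_c12", "or_c13"]

    def test_alpha_validated(self, toy_table):
        with pytest.raises(ValidationError):
            LabelScreen(toy_table, alpha=1.5)


class TestAggregate:
    def _calls(self, otus, direction="labelled"):
        from sipscreen.screen import BreslowDayResult, LabelCall

        bd = BreslowDayResult(1.0, 1, 0.001, 1.0, (1.0,), (1.0,))
        return [
            LabelCall(o, OddsRatioPair(1.0, 5.0), bd, 0.001, i + 1, 0.05, True, direction)
            for i, o in enumerate(otus)
        ]

    def _table(self, heavy13_counts):
        otus = list(heavy13_counts)
        counts = np.column_stack(
            [
                np.ones(len(otus), dtype=int),
                np.ones(len(otus), dtype=int),
                np.ones(len(otus), dtype=int),
                np.array(list(heavy13_counts.values())),
            ]
        )
        return SipCountTable(
            otu_ids=otus,
            sample_ids=["C12_light", "C12_heavy", "C13_light", "C13_heavy"],
            counts=counts,
            meta=four_sample_meta(),
        )

    def test_single_labelled_taxon_is_unity(self):
        tax = TaxonomyMap({"OtuA": ["Bacteria", "P1", "ClassA"]})
        table = self._table({"OtuA": 30, "OtuB": 99})
        agg = aggregate_labelled_taxa(self._calls(["OtuA"]), tax, "class", table)
        assert agg.to_dict() == {"ClassA": 1.0}

    def test_hand_normalisation_over_classes(self):
        tax = TaxonomyMap(
            {
                "OtuA": ["Bacteria", "P", "ClassA"],
                "OtuB": ["Bacteria", "P", "ClassA"],
                "OtuC": ["Bacteria", "P", "ClassB"],
            }
        )
        table = self._table({"OtuA": 30, "OtuB": 10, "OtuC": 60})
        agg = aggregate_labelled_taxa(
            self._calls(["OtuA", "OtuB", "OtuC"]), tax, "class", table
        )
        assert agg["ClassA"] == pytest.approx(0.4)
        assert agg["ClassB"] == pytest.approx(0.6)

    def test_no_labelled_taxa_empty(self):
        tax = TaxonomyMap()
        table = self._table({"OtuA": 30})
        agg = aggregate_labelled_taxa(
            self._calls(["OtuA"], direction="none"), tax, "class", table
        )
        assert agg.empty
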