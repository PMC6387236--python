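"""Paired transition statistics: McNemar, Bowker, distributions, triples."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from seatpose.classify import ParticipantResult, ParticipantStatus
from seatpose.postures import PostureLabel, RECOGNIZED
from seatpose.transitions import (
    BowkerResult,
    PostureTransitionModel,
    TransitionTable,
    TripleClass,
    bowker,
    build_transition_table,
    classify_triple,
    eligible_pairs,
    format_pvalue,
    interval_distribution,
    mcnemar_cc,
    significance_band,
    transition_report,
)

P = PostureLabel


def ok_result(pid, a, b, c):
    return ParticipantResult(pid, P.coerce(a), P.coerce(b), P.coerce(c),
                             ParticipantStatus.OK)


class TestMcNemar:
    @pytest.mark.parametrize(
        "b, c, statistic, p_display",
        [
            (9, 3, 25 / 12, 0.149),
            (1, 1, 0.5, 0.479),     # equal counts: no clamping, stat 1/(b+c)
            (1, 2, 0.0, 1.0),
            (3, 7, 0.9, 0.343),
            (21, 4, 10.24, 0.001),
            (7, 4, 4 / 11, 0.546),
            (7, 1, 3.125, 0.077),
        ],
    )
    def test_corrected_statistic_and_pvalue(self, b, c, statistic, p_display):
        res = mcnemar_cc(b, c)
        assert res.statistic == pytest.approx(statistic)
        assert format_pvalue(res.pvalue) == p_display

    def test_matches_statsmodels(self):
        """Independent oracle: statsmodels' corrected chi-square McNemar."""
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(9, 3), (1, 1), (1, 2), (21, 4), (7, 1), (5, 5), (0, 4)]:
            res = mcnemar_cc(b, c)
            sm = sm_mcnemar(np.array([[0, b], [c, 0]]), exact=False, correction=True)
            assert res.statistic == pytest.approx(float(sm.statistic))
            assert res.pvalue == pytest.approx(float(sm.pvalue))

    def test_no_discordant_pairs_errors(self):
        with pytest.raises(ValueError, match="discordant"):
            mcnemar_cc(0, 0)

    def test_exact_variant_is_binomial(self):
        res = mcnemar_cc(9, 3, variant="exact")
        from scipy.stats import binomtest

        assert res.pvalue == pytest.approx(binomtest(9, 12, 0.5).pvalue)

    @given(b=st.integers(0, 60), c=st.integers(0, 60))
    def test_symmetric_in_b_c(self, b, c):
        if b + c == 0:
            return
        lhs, rhs = mcnemar_cc(b, c), mcnemar_cc(c, b)
        assert lhs.statistic == rhs.statistic and lhs.pvalue == rhs.pvalue

    @given(n=st.integers(2, 80), d1=st.integers(0, 40), d2=st.integers(0, 40))
    def test_statistic_monotone_in_difference(self, n, d1, d2):
        """At fixed b + c the statistic grows with |b - c|."""
        d1, d2 = sorted((min(d1, n), min(d2, n)))
        if (n + d1) % 2 or (n + d2) % 2:
            return
        s1 = mcnemar_cc((n + d1) // 2, (n - d1) // 2).statistic
        s2 = mcnemar_cc((n + d2) // 2, (n - d2) // 2).statistic
        assert s1 <= s2 + 1e-12


class TestEligiblePairs:
    def test_reference_ti1_ti2_pairs(self, table_ti12):
        table = TransitionTable(table_ti12)
        names = {f"{a.value}-{b.value}" for a, b in eligible_pairs(table)}
        assert names == {"P1-P3", "P1-P6", "P1-P8", "P2-P4", "P6-P8"}

    def test_reference_ti2_ti3_pairs(self, table_ti23):
        table = TransitionTable(table_ti23)
        names = {f"{a.value}-{b.value}" for a, b in eligible_pairs(table)}
        assert names == {"P1-P6", "P1-P8", "P6-P8", "P7-P8"}

    def test_diagonal_table_has_none(self):
        assert eligible_pairs(TransitionTable(np.eye(8, dtype=int) * 3)) == []

    def test_one_sided_flow_excluded(self):
        t = np.zeros((8, 8), dtype=int)
        t[0, 1] = 5  # b=5, c=0: McNemar condition violated
        assert eligible_pairs(TransitionTable(t)) == []


class TestBowker:
    def test_symmetric_table_statistic_zero(self):
        t = np.full((8, 8), 2, dtype=int)
        res = bowker(TransitionTable(t))
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_single_discordant_pair(self):
        t = np.zeros((8, 8), dtype=int)
        t[0, 1] = 2
        res = bowker(TransitionTable(t))
        assert res == BowkerResult(statistic=2.0, df=1, pvalue=pytest.approx(0.1573, abs=1e-4))

    def test_brute_force_oracle_on_reference_table(self, table_ti23):
        """Direct double loop over all 28 cell pairs."""
        stat, df = 0.0, 0
        for i in range(8):
            for j in range(i + 1, 8):
                n = table_ti23[i, j] + table_ti23[j, i]
                if n > 0:
                    stat += (table_ti23[i, j] - table_ti23[j, i]) ** 2 / n
                    df += 1
        res = bowker(TransitionTable(table_ti23))
        assert res.statistic == pytest.approx(stat)
        assert res.df == df

    def test_equals_sum_of_uncorrected_mcnemar(self, table_ti12):
        table = TransitionTable(table_ti12)
        total = 0.0
        for i in range(8):
            for j in range(i + 1, 8):
                b, c = int(table_ti12[i, j]), int(table_ti12[j, i])
                if b + c > 0:
                    total += mcnemar_cc(b, c, variant="uncorrected").statistic
        assert bowker(table).statistic == pytest.approx(total)

    def test_fully_diagonal_errors(self):
        with pytest.raises(ValueError, match="diagonal"):
            bowker(TransitionTable(np.eye(8, dtype=int)))


class TestTransitionTable:
    def test_counts_from_results(self):
        results = [ok_result(i, "P1", "P1", "P1") for i in range(3)]
        table = build_transition_table(results, "TI1", "TI2")
        assert table.cell(P.P1, P.P1) == 3 and table.n == 3

    def test_empty_cohort_all_zero(self):
        table = build_transition_table([], "TI1", "TI2")
        assert table.n == 0

    def test_non_ok_result_rejected(self):
        bad = ParticipantResult(1, None, None, None, ParticipantStatus.SENSOR_FAILURE)
        with pytest.raises(ValueError, match="status"):
            build_transition_table([bad], "TI1", "TI2")

    def test_fixture_cohort_reproduces_reference_tables(
        self, fixture_cohort, table_ti12, table_ti23
    ):
        results = [ok_result(f.participant, *f.triple) for f in fixture_cohort]
        t12 = build_transition_table(results, "TI1", "TI2")
        t23 = build_transition_table(results, "TI2", "TI3")
        assert np.array_equal(t12.counts, table_ti12)
        assert np.array_equal(t23.counts, table_ti23)
        assert t12.cell(P.P1, P.P1) == 31 and t12.cell(P.P8, P.P1) == 7

    def test_margin_conservation(self, fixture_cohort):
        results = [ok_result(f.participant, *f.triple) for f in fixture_cohort]
        t12 = build_transition_table(results, "TI1", "TI2")
        t23 = build_transition_table(results, "TI2", "TI3")
        dist1 = interval_distribution(results, "TI1")
        n = len(results)
        for p in RECOGNIZED:
            assert t12.row_margin()[p] == pytest.approx(dist1[p] * n)
            assert t12.col_margin()[p] == t23.row_margin()[p]


class TestDistributionsAndTriples:
    def test_reference_shares(self, fixture_cohort):
        results = [ok_result(f.participant, *f.triple) for f in fixture_cohort]
        ti2 = interval_distribution(results, "TI2")
        ti3 = interval_distribution(results, "TI3")
        assert round(100 * ti2[P.P1]) == 53
        assert round(100 * ti3[P.P1]) == 30
        assert round(100 * (ti3[P.P6] + ti3[P.P7] + ti3[P.P8])) == 64

    def test_proportions_sum_to_one(self, fixture_cohort):
        results = [ok_result(f.participant, *f.triple) for f in fixture_cohort]
        for ti in ("TI1", "TI2", "TI3"):
            assert sum(interval_distribution(results, ti).values()) == pytest.approx(1.0)

    def test_single_participant(self):
        dist = interval_distribution([ok_result(1, "P1", "P1", "P1")], "TI1")
        assert dist[P.P1] == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no participants"):
            interval_distribution([], "TI1")

    @pytest.mark.parametrize(
        "triple, expected",
        [
            (("P1", "P1", "P1"), TripleClass.NO_TRANSITION),
            (("P1", "P6", "P1"), TripleClass.NON_MONOTONIC),
            (("P1", "P6", "P8"), TripleClass.MONOTONIC),
            (("P1", "P1", "P6"), TripleClass.MONOTONIC),
            (("P1", "P6", "P6"), TripleClass.MONOTONIC),
        ],
    )
    def test_triple_classification(self, triple, expected):
        assert classify_triple(triple) is expected


class TestDisplayConventions:
    @pytest.mark.parametrize(
        "p, shown",
        [
            (0.4795001221, 0.479),  # exact trailing 5 drops, never rounds up
            (0.5464936, 0.546),
            (0.1489147, 0.149),
            (0.3427817, 0.343),
            (0.0013743, 0.001),
            (0.0770999, 0.077),
            (0.0002, 0.0002),       # below 0.001: four decimals
            (1.0, 1.0),
        ],
    )
    def test_format_pvalue(self, p, shown):
        assert format_pvalue(p) == shown

    def test_bands(self):
        assert significance_band(0.01) == "significant"
        assert significance_band(0.077) == "notable"
        assert significance_band(0.149) == "ns"


class TestModelResults:
    @pytest.fixture()
    def fitted(self, fixture_cohort):
        model = PostureTransitionModel.from_triples([f.triple for f in fixture_cohort])
        return model.fit()

    def test_reference_pvalues(self, fitted):
        shown = {
            key: {t.pair_name: format_pvalue(t.pvalue) for t in tests}
            for key, tests in fitted.mcnemar.items()
        }
        assert shown["TI1-TI2"] == {
            "P1-P3": 1.0, "P1-P6": 0.149, "P1-P8": 0.343,
            "P2-P4": 0.479, "P6-P8": 0.479,
        }
        assert shown["TI2-TI3"] == {
            "P1-P6": 0.001, "P1-P8": 0.546, "P6-P8": 0.077, "P7-P8": 0.479,
        }

    def test_report_blocks_and_determinism(self, fixture_cohort):
        results = [ok_result(f.participant, *f.triple) for f in fixture_cohort]
        a = transition_report(results)
        b = transition_report(results)
        assert a == b
        assert set(a) == {
            "n_participants", "transition_tables", "mcnemar", "bowker",
            "distributions", "triples",
        }
        assert len(a["mcnemar"]["TI1-TI2"]) == 5
        assert len(a["mcnemar"]["TI2-TI3"]) == 4

    def test_cohort_of_one(self):
        report = transition_report([ok_result(1, "P1", "P1", "P1")])
        assert report["n_participants"] == 1
        assert report["mcnemar"]["TI1-TI2"] == []

    def test_summary_mentions_key_results(self, fitted):
        text = fitted.summary()
        assert "Participants: 83" in text
        assert "P1-P6" in text and "Bowker" in text

    def test_model_rejects_non_ok(self):
        bad = ParticipantResult(9, None, None, None, ParticipantStatus.SENSOR_FAILURE)
        with pytest.raises(ValueError, match="non-OK"):
            PostureTransitionModel([bad])

    def test_plot_smoke(self, fitted):
        import matplotlib

        matplotlib.use("Agg")
        ax = fitted.plot_transition_graph()
        assert ax is not None
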