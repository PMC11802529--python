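"""ROR/PRR estimators: hand oracles, statsmodels cross-check, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepavigil import (
    AggregateCountTable,
    ValidationError,
    build_contingency,
    forest_data,
    prr,
    ror,
    screen,
    signal_frame,
)
from hepavigil.data_model import UnknownTermError, aggregate
from hepavigil.disproportionality import ContingencyTable, plot_forest
from hepavigil.synthetic_srs import default_config, generate

from conftest import GI, random_tables

cells = st.integers(min_value=1, max_value=1_000_000)


class TestBuildContingency:
    def test_fixture_liraglutide_gi_cells(self, paper):
        """Hand summation of the 27-SOC table: b is liraglutide's total
        occurrences minus a, c the GI column over the other four drugs."""
        ct = build_contingency(paper.table3, "liraglutide", GI, level="soc")
        assert (ct.a, ct.b, ct.c, ct.d) == (28_252, 68_299, 10_191, 113_926)

    def test_two_drug_toy_direct_placement(self, toy_dictionary):
        table = AggregateCountTable(
            drugs=["X", "Y"],
            n_reports={"X": 10, "Y": 100},
            pt_counts={("X", "t"): 3, ("X", "u"): 7, ("Y", "t"): 30, ("Y", "u"): 70},
        )
        ct = build_contingency(table, "X", "t", level="pt")
        assert (ct.a, ct.b, ct.c, ct.d) == (3, 7, 30, 70)

    def test_grand_total_conservation(self, paper):
        grand = sum(paper.table3.soc_counts.values())
        for drug in paper.table3.drugs:
            ct = build_contingency(paper.table3, drug, GI, level="soc")
            assert ct.grand_total == grand

    def test_single_drug_dataset_has_no_comparator(self, toy_dictionary):
        table = AggregateCountTable(
            drugs=["X"], n_reports={"X": 5}, soc_counts={("X", GI): 5}
        )
        with pytest.raises(ValidationError, match="comparator"):
            build_contingency(table, "X", GI, level="soc")

    def test_unknown_term_raises(self, paper):
        with pytest.raises(UnknownTermError):
            build_contingency(paper.table3, "liraglutide", "Not a SOC", level="soc")

    def test_report_mode_at_soc_level_needs_report_counts(self, paper):
        with pytest.raises(ValidationError, match="soc_report_counts"):
            build_contingency(paper.table3, "liraglutide", GI, level="soc", mode="report")

    def test_report_mode_from_reports_uses_report_totals(self):
        config = default_config(n_reports=2_000, seed=23)
        table = aggregate(generate(config), config.dictionary())
        drug = table.drugs[0]
        ct = build_contingency(table, drug, "Nausea", level="pt", mode="report")
        assert ct.a + ct.b == table.n_reports[drug]
        ct_soc = build_contingency(table, drug, GI, level="soc", mode="report")
        assert ct_soc.a + ct_soc.b == table.n_reports[drug]
        assert ct_soc.a <= table.soc_counts[(drug, GI)]


class TestHandOracles:
    def test_null_table_is_exactly_one_with_log_symmetric_ci(self):
        est = ror(ContingencyTable(10, 10, 10, 10))
        assert est.estimate == 1.0
        assert est.ci_low * est.ci_high == pytest.approx(1.0, rel=1e-12)
        assert not est.significant

    def test_ror_hand_arithmetic(self):
        # (3 * 970) / (97 * 30) = 1
        est = ror(ContingencyTable(3, 97, 30, 970))
        assert est.estimate == pytest.approx(1.0, rel=1e-12)

    def test_prr_equal_proportions_is_one(self):
        est = prr(ContingencyTable(10, 90, 100, 900))
        assert est.estimate == pytest.approx(1.0, rel=1e-12)

    def test_prr_hand_arithmetic(self):
        # (10/100) / (10/200) = 2
        est = prr(ContingencyTable(10, 90, 10, 190))
        assert est.estimate == pytest.approx(2.0, rel=1e-12)

    def test_fixture_reproduces_published_gi_ror(self, paper):
        ct = build_contingency(paper.table3, "liraglutide", GI, level="soc")
        est = ror(ct)
        assert est.estimate == pytest.approx(4.629, rel=0.01)
        assert est.ci_low == pytest.approx(4.517, rel=0.01)
        assert est.ci_high == pytest.approx(4.744, rel=0.01)
        assert est.significant

    def test_fixture_reproduces_published_gi_prr(self, paper):
        ct = build_contingency(paper.table3, "liraglutide", GI, level="soc")
        est = prr(ct)
        assert est.estimate == pytest.approx(3.566, rel=0.01)
        assert est.ci_low == pytest.approx(3.492, rel=0.01)
        assert est.ci_high == pytest.approx(3.642, rel=0.01)
        assert est.significant


class TestStatsmodelsOracle:
    """Independent recomputation via statsmodels' generic 2x2 machinery."""

    def test_matches_table2x2(self):
        from statsmodels.stats.contingency_tables import Table2x2

        rng = np.random.default_rng(42)
        for ct in random_tables(rng, 50):
            sm = Table2x2(np.array([[ct.a, ct.b], [ct.c, ct.d]]))
            r = ror(ct)
            assert r.estimate == pytest.approx(sm.oddsratio, rel=1e-10)
            lo, hi = sm.oddsratio_confint(alpha=0.05)
            assert r.ci_low == pytest.approx(lo, rel=1e-3)
            assert r.ci_high == pytest.approx(hi, rel=1e-3)
            p = prr(ct)
            assert p.estimate == pytest.approx(sm.riskratio, rel=1e-10)
            lo, hi = sm.riskratio_confint(alpha=0.05)
            assert p.ci_low == pytest.approx(lo, rel=1e-3)
            assert p.ci_high == pytest.approx(hi, rel=1e-3)


class TestEstimatorInvariants:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_swap_inverts_ror_and_exchanges_ci(self, a, b, c, d):
        ct = ContingencyTable(a, b, c, d)
        fwd, rev = ror(ct), ror(ct.swapped())
        assert rev.estimate == pytest.approx(1.0 / fwd.estimate, rel=1e-12)
        assert rev.ci_low == pytest.approx(1.0 / fwd.ci_high, rel=1e-12)
        assert rev.ci_high == pytest.approx(1.0 / fwd.ci_low, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(2, 50))
    def test_scaling_preserves_points_and_narrows_cis(self, a, b, c, d, k):
        ct = ContingencyTable(a, b, c, d)
        scaled = ContingencyTable(k * a, k * b, k * c, k * d)
        for func in (ror, prr):
            base, big = func(ct), func(scaled)
            assert big.estimate == pytest.approx(base.estimate, rel=1e-12)
            assert (big.ci_high / big.ci_low) < (base.ci_high / base.ci_low)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ror_is_farther_from_one_than_prr(self, a, b, c, d):
        ct = ContingencyTable(a, b, c, d)
        lr, lp = math.log(ror(ct).estimate), math.log(prr(ct).estimate)
        assert lr * lp >= -1e-15  # same side of 1
        assert abs(lr) >= abs(lp) - 1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_log_space_recomputation(self, a, b, c, d):
        ct = ContingencyTable(a, b, c, d)
        lror = math.log(a) + math.log(d) - math.log(b) - math.log(c)
        assert math.log(ror(ct).estimate) == pytest.approx(lror, abs=1e-12)
        lprr = (math.log(a) - math.log(a + b)) - (math.log(c) - math.log(c + d))
        assert math.log(prr(ct).estimate) == pytest.approx(lprr, abs=1e-12)


class TestZeroCellsAndSignificance:
    def test_zero_cell_triggers_flagged_correction(self):
        est = ror(ContingencyTable(5, 95, 0, 100))
        assert est.correction_applied
        assert est.estimate == pytest.approx((5.5 * 100.5) / (95.5 * 0.5), rel=1e-12)
        assert est.evaluable  # a = 5 >= 3

    def test_zero_cell_with_few_cases_not_evaluable(self):
        est = ror(ContingencyTable(2, 98, 0, 100))
        assert est.correction_applied and not est.evaluable and not est.significant

    def test_two_cases_never_flagged_even_with_huge_ratio(self):
        for metric in (ror, prr):
            est = metric(ContingencyTable(2, 10, 1, 10_000))
            assert est.estimate > 2 and not est.significant

    def test_three_cases_with_clear_signal_always_flagged(self):
        est = ror(ContingencyTable(30, 100, 10, 1_000))
        assert est.estimate > 2 and est.ci_low > 1 and est.significant
        assert prr(ContingencyTable(30, 100, 10, 1_000)).significant

    def test_ror_above_2_but_ci_straddling_1_not_flagged(self):
        # a=3: wide CI crosses 1 although the point estimate exceeds 2
        est = ror(ContingencyTable(3, 100, 10, 1_000))
        assert est.estimate > 2 and est.ci_low < 1 and not est.significant


@pytest.fixture(scope="module")
def screen_table():
    config = default_config(n_reports=3_000, seed=31)
    return aggregate(generate(config), config.dictionary())


class TestScreen:
    @pytest.fixture
    def table(self, screen_table):
        return screen_table

    def test_matches_per_pair_recomputation(self, table):
        rows = screen(table, level="pt", metrics=("ROR",))
        for row in rows:
            ct = build_contingency(table, row.drug, row.term, level="pt")
            assert row.estimate.estimate == ror(ct).estimate

    def test_ordered_by_drug_then_term(self, table):
        rows = screen(table, level="pt", metrics=("ROR",))
        keys = [(r.drug, r.term) for r in rows]
        assert keys == sorted(keys)

    def test_small_counts_not_evaluable(self, toy_dictionary):
        table = AggregateCountTable(
            drugs=["X", "Y"],
            n_reports={"X": 100, "Y": 100},
            pt_counts={("X", "t"): 2, ("X", "u"): 98, ("Y", "t"): 1, ("Y", "u"): 99},
        )
        rows = screen(table, level="pt", metrics=("ROR",))
        xt = next(r for r in rows if (r.drug, r.term) == ("X", "t"))
        assert not xt.estimate.evaluable and not xt.estimate.significant

    def test_fixture_screen_flags_liraglutide_gi_on_both_metrics(self, paper):
        rows = screen(paper.table3, level="soc")
        assert len({(r.drug, r.term) for r in rows}) <= 5 * 27
        flagged = {
            r.metric for r in rows if (r.drug, r.term) == ("liraglutide", GI)
            if r.estimate.significant
        }
        assert flagged == {"ROR", "PRR"}

    def test_signal_frame_columns(self, table):
        frame = signal_frame(screen(table, level="pt"))
        assert list(frame.columns[:8]) == ["drug", "term", "level", "metric", "a", "b", "c", "d"]


class TestForest:
    def test_fixture_gi_forest_puts_liraglutide_first(self, paper):
        rows = [
            r
            for r in screen(paper.table3, level="soc", metrics=("ROR",))
            if r.term == GI
        ]
        frame = forest_data(rows)
        assert len(frame) == 5
        assert frame.iloc[0]["label"].startswith("liraglutide")
        assert (frame["reference"] == 1.0).all()

    def test_mixed_metrics_rejected(self, paper):
        rows = screen(paper.table3, level="soc")
        with pytest.raises(ValidationError, match="single metric"):
            forest_data(rows)

    def test_empty_input_gives_valid_empty_export(self, tmp_path):
        frame = forest_data([])
        path = tmp_path / "forest.tsv"
        frame.to_csv(path, sep="\t", index=False)
        assert path.read_text().startswith("label\t")

    def test_tsv_roundtrip(self, paper, tmp_path):
        import pandas as pd

        rows = [
            r
            for r in screen(paper.table3, level="soc", metrics=("ROR",))
            if r.term == GI
        ]
        frame = forest_data(rows)
        path = tmp_path / "forest.tsv"
        frame.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, frame)

    def test_plot_writes_svg(self, paper, tmp_path):
        rows = [
            r
            for r in screen(paper.table3, level="soc", metrics=("ROR",))
            if r.term == GI
        ]
        path = tmp_path / "forest.svg"
        plot_forest(forest_data(rows), str(path))
        assert path.stat().st_size > 0
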