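"""Contingency construction, the four statistics, thresholds and ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from faersig import signal_engine as se
from faersig.signal_engine import (
    SignalStats,
    TwoByTwo,
    build_table,
    classify_signal,
    compute_ebgm,
    compute_ic,
    compute_prr_chi2,
    compute_ror,
    compute_stats,
    rank_results,
    screen_pts,
    signal_table,
)

cells = st.integers(min_value=1, max_value=1000)
tables = st.tuples(cells, cells, cells, cells)


class TestFormulas:
    def test_worked_example(self):
        # (10, 90, 100, 9900): direct arithmetic on the printed formulas
        ror, lo, hi = compute_ror(10, 90, 100, 9900)
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(5.5597, abs=1e-3)
        assert hi == pytest.approx(21.762, abs=1e-2)
        prr, _, _, chi2 = compute_prr_chi2(10, 90, 100, 9900)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.446, abs=1e-2)
        ic, _ = compute_ic(10, 90, 100, 9900)
        assert ic == pytest.approx(math.log2(9.18181818), abs=1e-6)
        ebgm, _, _ = compute_ebgm(10, 90, 100, 9900)
        assert ebgm == pytest.approx(9.18181818, abs=1e-6)
        assert 2.0 ** ic == pytest.approx(ebgm, rel=1e-12)

    def test_null_table_all_statistics_at_independence(self):
        ror, lo, hi = compute_ror(5, 5, 5, 5)
        assert ror == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale
        prr, _, _, chi2 = compute_prr_chi2(5, 5, 5, 5)
        assert prr == pytest.approx(1.0) and chi2 == pytest.approx(0.0)
        ic, _ = compute_ic(5, 5, 5, 5)
        assert ic == pytest.approx(0.0)
        ebgm, _, _ = compute_ebgm(5, 5, 5, 5)
        assert ebgm == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None)
    @given(tables)
    def test_ic_ebgm_identity_and_ordering(self, t):
        a, b, c, d = t
        ic, _ = compute_ic(a, b, c, d)
        ebgm, _, _ = compute_ebgm(a, b, c, d)
        assert 2.0 ** float(ic) == pytest.approx(float(ebgm), rel=1e-12)
        ror, _, _ = compute_ror(a, b, c, d)
        prr, _, _, _ = compute_prr_chi2(a, b, c, d)
        det = a * d - b * c
        if det > 0:
            assert ror > prr > ebgm > 1
        elif det < 0:
            assert ror < prr < ebgm < 1
        else:
            assert float(ror) == pytest.approx(1.0)
            assert float(prr) == pytest.approx(1.0)
            assert float(ebgm) == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(tables)
    def test_chi2_matches_pearson_oracle_and_symmetry(self, t):
        a, b, c, d = t
        _, _, _, chi2 = compute_prr_chi2(a, b, c, d)
        oracle = chi2_contingency([[a, b], [c, d]], correction=False).statistic
        assert float(chi2) == pytest.approx(oracle, rel=1e-9)
        # swapping both rows and both columns leaves chi2 unchanged
        _, _, _, swapped = compute_prr_chi2(d, c, b, a)
        assert float(swapped) == pytest.approx(float(chi2), rel=1e-12)

    def test_ci_coverage_on_simulated_null_tables(self):
        # independence tables with margins >= 50: the ROR lower bound should
        # exceed 1 in at most ~2.5% of draws (one tail of a 95% interval)
        rng = np.random.default_rng(20240915)
        n_sim, n_reports = 1000, 4000
        flagged = 0
        p_drug, p_event = 0.05, 0.05
        for _ in range(n_sim):
            x = rng.multinomial(n_reports, [
                p_drug * p_event, p_drug * (1 - p_event),
                (1 - p_drug) * p_event, (1 - p_drug) * (1 - p_event)])
            a, b, c, d = (int(v) for v in x)
            if min(a, b, c, d) == 0:
                continue
            _, lo, _ = compute_ror(a, b, c, d)
            if lo > 1:
                flagged += 1
        bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)
        assert flagged / n_sim <= bound


class TestStatsAndClassification:
    def test_zero_cell_correction_flags_and_keeps_finite(self):
        t = TwoByTwo(a=3, b=0, c=4, d=100)
        s = compute_stats(t)
        assert s.zero_cell_corrected
        assert all(np.isfinite([s.ror, s.ror_low, s.ror_high, s.ic, s.ebgm]))
        assert s.n_reported == 3

    def test_zero_observed_count_is_undefined(self):
        s = compute_stats(TwoByTwo(a=0, b=5, c=5, d=5))
        assert s.reason == "zero_observed_count"
        d = classify_signal(s)
        assert not (d.ror_positive or d.prr_positive or d.bcpnn_positive
                    or d.ebgm_positive) and not d.all_four
        assert d.reason == "zero_observed_count"

    def test_correction_disabled_returns_reason(self):
        s = compute_stats(TwoByTwo(a=3, b=0, c=4, d=100), zero_cell_correction=False)
        assert s.reason == "zero_cell_uncorrected"

    def test_below_frequency_screen_never_fires(self):
        # a = 2 with an enormous ROR: every rule stays negative
        s = compute_stats(TwoByTwo(a=2, b=1, c=1, d=10000))
        assert s.ror > 100
        d = classify_signal(s)
        assert not d.ror_positive and not d.prr_positive
        assert not d.bcpnn_positive and not d.ebgm_positive

    def test_all_thresholds_met_gives_conjunction(self):
        d = classify_signal(compute_stats(TwoByTwo(a=50, b=50, c=100, d=9800)))
        assert d.ror_positive and d.prr_positive and d.bcpnn_positive
        assert d.ebgm_positive and d.all_four

    def test_ic025_exactly_zero_is_negative(self):
        s = SignalStats(ror=2, ror_low=1.5, ror_high=3, prr=2, prr_low=1.5,
                        prr_high=3, chi2=10, ic=1.0, ic025=0.0, ebgm=2.5,
                        ebgm05=2.1, ebgm95=3.0, n_reported=10)
        assert not classify_signal(s).bcpnn_positive

    def test_batch_decisions_match_rule_by_rule_recheck(self):
        rng = np.random.default_rng(7)
        mismatches = 0
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(1, 400, size=4))
            s = compute_stats(TwoByTwo(a=a, b=b, c=c, d=d))
            dec = classify_signal(s)
            # independent recheck straight from the threshold statements
            ror_ok = a >= 3 and s.ror_low > 1
            prr_ok = a >= 3 and s.prr >= 2 and s.chi2 >= 4
            bcpnn_ok = a >= 3 and s.ic025 > 0
            ebgm_ok = a >= 3 and s.ebgm05 > 2
            expect_all = ror_ok and prr_ok and bcpnn_ok and ebgm_ok
            if (dec.ror_positive, dec.prr_positive, dec.bcpnn_positive,
                    dec.ebgm_positive, dec.all_four) != (
                    ror_ok, prr_ok, bcpnn_ok, ebgm_ok, expect_all):
                mismatches += 1
        assert mismatches == 0


def _pairs(rows):
    return pd.DataFrame(rows, columns=["report", "drug", "event"])


class TestBuildTable:
    def test_fixture_counts_match_nested_loop(self):
        rows = []
        for i in range(20):
            drug = "target" if i < 4 else "other"
            rows.append((f"r{i}", drug, "sopor" if i in (0, 1, 5, 6, 7) else "nausea"))
        pairs = _pairs(rows)
        t = build_table(pairs, "target", "sopor")
        # brute-force scan
        a = sum(1 for r in rows if r[1] == "target" and r[2] == "sopor")
        b = sum(1 for r in rows if r[1] == "target" and r[2] != "sopor")
        c = sum(1 for r in rows if r[1] != "target" and r[2] == "sopor")
        d = len(rows) - a - b - c
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d) == (2, 2, 3, 13)

    def test_absent_event_margin_conservation(self):
        pairs = _pairs([("r1", "target", "nausea"), ("r2", "other", "rash")])
        t = build_table(pairs, "target", "sopor")
        assert t.a == 0 and t.c == 0
        assert t.a + t.b + t.c + t.d == len(pairs)

    def test_single_report_degenerate(self):
        t = build_table(_pairs([("r1", "target", "sopor")]), "target", "sopor")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)

    def test_empty_dataset_is_error(self):
        with pytest.raises(ValueError, match="empty dataset"):
            build_table(_pairs([]), "x", "y")

    def test_repeated_pt_within_report_counts_once(self):
        pairs = pd.concat([_pairs([("r1", "target", "sopor")])] * 3)
        t = build_table(pairs, "target", "sopor")
        assert t.a == 1


class TestScreenAndRank:
    def test_frequency_screen_boundary(self):
        rows = ([(f"r{i}", "t", "freq3") for i in range(3)]
                + [(f"s{i}", "t", "freq2") for i in range(2)]
                + [("z", "o", "freq3")])
        out = screen_pts(_pairs(rows), "t")
        assert list(out["event"]) == ["freq3"]
        assert list(out["a"]) == [3]

    def _results(self):
        return pd.DataFrame({
            "event": ["w", "x", "y", "z"],
            "a": [500, 400, 301, 200],
            "ebgm": [2.0, 8.0, 8.0, 4.0],
        })

    def test_rank_by_cases_with_min_filter(self):
        out = rank_results(self._results(), by="case_count", min_cases=300)
        assert list(out["event"]) == ["w", "x", "y"]
        assert list(out["a"]) == [500, 400, 301]

    def test_rank_by_ebgm_top_k_and_alphabetical_ties(self):
        out = rank_results(self._results(), by="ebgm", top_k=3)
        assert list(out["event"]) == ["x", "y", "z"]  # tie x/y broken by name

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="ranking key"):
            rank_results(self._results(), by="prr")


class TestSignalTableVectorization:
    def test_matches_per_table_scalar_path(self, tiny_config):
        from faersig import cli_pipeline as cp
        from faersig import synthetic_faers as sf

        cfg = tiny_config(seed=3, n_reports=120)
        res = sf.generate(cfg)
        ana = cp.analyze_records(res.data, "drug_a", sf.synonym_map(cfg))
        table = ana.pt_table
        assert len(table) > 0
        for _, row in table.iterrows():
            t = build_table(ana.pairs, "drug_a", row["event"])
            s = compute_stats(t)
            dec = classify_signal(s)
            assert row["a"] == t.a
            for col, val in (("ror", s.ror), ("prr", s.prr), ("chi2", s.chi2),
                             ("ic", s.ic), ("ic025", s.ic025), ("ebgm", s.ebgm),
                             ("ebgm05", s.ebgm05)):
                assert row[col] == pytest.approx(val, rel=1e-12)
            assert bool(row["all_four"]) == dec.all_four
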