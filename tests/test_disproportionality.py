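"""PRR, chi-squared and the Evans positive-signal criterion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from pharmsig.disproportionality import (
    ContingencyTable,
    UndefinedStatisticError,
    build_contingency,
    classify_signal,
    compute_chi2,
    compute_prr,
)
from pharmsig.models import ReportSet
from pharmsig.synthetic import SyntheticConfig, generate_reports
from pharmsig.vocabulary import EventDefinition


cells = st.integers(min_value=0, max_value=500)


class TestBuildContingency:
    def test_direct_count(self, small_reports, small_vocab, gout_event):
        t = build_contingency(small_reports, small_vocab, "furosemide", gout_event)
        assert (t.a, t.b, t.c, t.d) == (2, 3, 1, 4)
        assert t.n == len(small_reports)

    def test_absent_drug_empty_exposed_row(self, small_reports, small_vocab, gout_event):
        t = build_contingency(
            small_reports, small_vocab,
            "Hyzaar (losartan potassium and hydrochlorothiazide)", gout_event,
        )
        assert (t.a, t.b) == (0, 0)
        assert t.c + t.d == len(small_reports)

    def test_empty_reportset_rejected(self, small_vocab, gout_event):
        with pytest.raises(ValueError, match="background"):
            build_contingency(ReportSet([]), small_vocab, "furosemide", gout_event)

    def test_matches_brute_force_recount(self, small_vocab):
        """Independent per-report recount on 200 random synthetic reports."""
        config = SyntheticConfig(
            n_reports=200,
            drug_catalog=small_vocab,
            pt_catalog=["gout", "nausea", "headache"],
            drug_marginals={"furosemide": 0.3, "losartan": 0.4, "amlodipine": 0.3},
            background_event_prob=0.2,
            planted=[("furosemide", "gout", 3.0)],
            seed=7,
        )
        reports = generate_reports(config)
        event = EventDefinition("gout", ["gout"])

        # oracle: its own normalization + synonym dictionary lookup
        syn = {}
        for e in small_vocab.entries:
            for name in (e.canonical, *e.synonyms):
                syn[" ".join(name.split()).lower()] = e.canonical
        a = b = c = d = 0
        for rec in reports:
            has_drug = any(
                syn.get(" ".join(m.split()).lower()) == "furosemide"
                for m in rec.drug_mentions
            )
            has_event = any(pt.lower() == "gout" for pt in rec.reaction_pts)
            if has_drug and has_event:
                a += 1
            elif has_drug:
                b += 1
            elif has_event:
                c += 1
            else:
                d += 1

        t = build_contingency(reports, small_vocab, "furosemide", event)
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)


class TestComputePrr:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((10, 90, 10, 90), 1.0),
            ((4, 96, 2, 98), 2.0),     # event twice as frequent with the drug
            ((5, 95, 100, 9900), 5.0),
            ((0, 10, 5, 85), 0.0),
        ],
    )
    def test_values(self, table, expected):
        assert compute_prr(ContingencyTable(*table)) == pytest.approx(expected)

    def test_zero_background_cases_infinite(self):
        assert compute_prr(ContingencyTable(3, 7, 0, 90)) == math.inf

    def test_empty_row_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            compute_prr(ContingencyTable(0, 0, 5, 95))

    def test_haldane_continuity_keeps_prr_finite(self):
        prr = compute_prr(ContingencyTable(3, 7, 0, 90), continuity=0.5)
        assert math.isfinite(prr) and prr > 1

    @given(a=st.integers(0, 200), b=st.integers(1, 500), c=st.integers(1, 500), d=cells)
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_a(self, a, b, c, d):
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + 1, b, c, d)
        assert compute_prr(t2) >= compute_prr(t1)


class TestComputeChi2:
    def test_proportional_table_is_zero(self):
        assert compute_chi2(ContingencyTable(10, 90, 20, 180), yates=False) == 0.0

    def test_closed_form_value(self):
        # 1100 * (20*900 - 80*100)^2 / (100 * 1000 * 120 * 980)
        t = ContingencyTable(20, 80, 100, 900)
        expected = 1100 * 10000**2 / (100 * 1000 * 120 * 980)
        assert compute_chi2(t, yates=False) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.3537, abs=1e-4)

    def test_transpose_symmetry(self):
        t = ContingencyTable(20, 80, 100, 900)
        swapped_rows = ContingencyTable(100, 900, 20, 80)
        transposed = ContingencyTable(20, 100, 80, 900)
        for variant in (swapped_rows, transposed):
            for yates in (True, False):
                assert compute_chi2(t, yates) == pytest.approx(
                    compute_chi2(variant, yates)
                )

    def test_yates_floors_at_zero(self):
        # |ad - bc| = 2 <= n/2 = 8 -> corrected statistic is 0
        t = ContingencyTable(2, 3, 4, 7)
        assert compute_chi2(t, yates=True) == 0.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            compute_chi2(ContingencyTable(0, 0, 10, 90))
        with pytest.raises(UndefinedStatisticError):
            compute_chi2(ContingencyTable(0, 10, 0, 90))

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=300, deadline=None)
    def test_matches_scipy_oracle(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        obs = np.array([[a, b], [c, d]])
        for yates in (False, True):
            ref = chi2_contingency(obs, correction=yates).statistic
            assert compute_chi2(t, yates=yates) == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_cellwise_oracle_on_random_tables(self):
        """Pearson statistic equals the cell-wise sum((O-E)^2/E) form."""
        rng = np.random.default_rng(42)
        tables = rng.integers(0, 400, size=(1000, 4))
        checked = 0
        for a, b, c, d in tables:
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            obs = np.array([[a, b], [c, d]], dtype=float)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            stat = ((obs - expected) ** 2 / expected).sum()
            assert compute_chi2(t, yates=False) == pytest.approx(stat, rel=1e-9)
            checked += 1
        assert checked > 900


class TestClassifySignal:
    @pytest.mark.parametrize(
        "n,prr,chi2,expected",
        [
            (3, 2.0, 4.0, True),     # all boundaries inclusive
            (2, 10.0, 50.0, False),  # below case minimum
            (5, 1.99, 30.0, False),  # PRR below threshold
            (5, 2.0, 3.99, False),   # chi2 below threshold
            (100, 50.0, 500.0, True),
            (3, math.inf, 4.0, True),
            (0, 0.0, 0.0, False),
        ],
    )
    def test_boundary_grid(self, n, prr, chi2, expected):
        assert classify_signal(n, prr, chi2) is expected

    @given(
        n=st.integers(0, 6),
        prr=st.sampled_from([0.0, 1.99, 2.0, 2.01, 10.0]),
        chi2=st.sampled_from([0.0, 3.99, 4.0, 4.01, 50.0]),
    )
    def test_equals_conjunction(self, n, prr, chi2):
        assert classify_signal(n, prr, chi2) == (n >= 3 and prr >= 2 and chi2 >= 4)
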