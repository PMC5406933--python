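"""Expected counts, chi-square statistics, p-values and the contig contrast."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.special import gamma as gamma_fn

from sialomine import (
    Contrast,
    chisq_2x2,
    chisq_gof,
    chisq_pvalue,
    diff_table,
    expected_counts,
)

from conftest import make_catalogue


class TestExpectedCounts:
    def test_symmetric_depths_split_evenly(self):
        assert expected_counts(10, (500, 500)) == (5.0, 5.0)

    def test_hand_arithmetic(self):
        ea, eb = expected_counts(65, (3000, 3400))
        assert ea == pytest.approx(65 * 3000 / 6400)  # 30.46875
        assert eb == pytest.approx(65 * 3400 / 6400)

    @given(
        total=st.integers(1, 10_000),
        na=st.integers(1, 100_000),
        nb=st.integers(1, 100_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation(self, total, na, nb):
        ea, eb = expected_counts(total, (na, nb))
        assert ea + eb == pytest.approx(total, abs=1e-9)
        assert ea >= 0 and eb >= 0

    def test_zero_condition_total_rejected(self):
        with pytest.raises(ValueError):
            expected_counts(10, (0, 100))


class TestChisqGof:
    def test_null_identity(self):
        chi2, df = chisq_gof([4, 6, 10], [4, 6, 10])
        assert chi2 == 0.0 and df == 2

    def test_closed_form_two_cells(self):
        chi2, df = chisq_gof([10, 0], [5, 5])
        assert chi2 == pytest.approx(10.0) and df == 1

    def test_matches_brute_force_sum(self):
        obs = [5, 27]
        ea, eb = expected_counts(32, (3000, 3500))
        chi2, _ = chisq_gof(obs, [ea, eb])
        brute = sum((o - e) ** 2 / e for o, e in zip(obs, [ea, eb]))
        assert chi2 == pytest.approx(brute)

    def test_mismatched_sums_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            chisq_gof([10, 10], [5, 5])


class TestChisq2x2:
    @given(
        a=st.integers(0, 50),
        b=st.integers(0, 50),
        na=st.integers(100, 5000),
        nb=st.integers(100, 5000),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_textbook_margin_formula(self, a, b, na, nb):
        """N(ad-bc)^2 over the four margin products."""
        c, d = na - a, nb - b
        n = na + nb
        if a + b == 0 or c + d == 0:
            return
        chi2, df = chisq_2x2((a, b), (na, nb), yates=False)
        oracle = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * na * nb)
        assert df == 1
        assert chi2 == pytest.approx(oracle, rel=1e-9)

    def test_proportional_counts_give_zero(self):
        chi2, _ = chisq_2x2((10, 10), (1000, 1000))
        assert chi2 == pytest.approx(0.0)

    @given(a=st.integers(1, 40), b=st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_yates_never_exceeds_uncorrected(self, a, b):
        plain, _ = chisq_2x2((a, b), (500, 700), yates=False)
        corrected, _ = chisq_2x2((a, b), (500, 700), yates=True)
        assert corrected <= plain + 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2((0, 0), (100, 100))


def _pvalue_by_quadrature(chi2, df):
    """Independent oracle: numeric integration of the chi-square density."""
    dens = lambda x: x ** (df / 2 - 1) * np.exp(-x / 2) / (2 ** (df / 2) * gamma_fn(df / 2))
    val, _ = integrate.quad(dens, chi2, np.inf)
    return val


class TestChisqPvalue:
    def test_zero_statistic_gives_one(self):
        assert chisq_pvalue(0.0, 1) == 1.0

    @pytest.mark.parametrize("chi2,df", [(3.841, 1), (5.991, 2), (0.5, 1), (20.0, 7)])
    def test_agrees_with_numeric_integration(self, chi2, df):
        assert chisq_pvalue(chi2, df) == pytest.approx(_pvalue_by_quadrature(chi2, df), abs=1e-6)

    def test_critical_value_at_five_percent(self):
        assert chisq_pvalue(3.841, 1) == pytest.approx(0.05, abs=1e-3)

    @pytest.mark.parametrize(
        "chi2,printed_p",
        [(4.531, 0.033), (7.343, 0.007)],
    )
    def test_reported_statistics_reproduce_printed_p(self, chi2, printed_p):
        """The published per-contig statistics are internally consistent at df=1."""
        assert round(chisq_pvalue(chi2, 1), 3) == printed_p

    def test_large_statistic_below_point_001(self):
        assert chisq_pvalue(10.864, 1) < 0.001

    def test_monotone_decreasing_in_chi2(self):
        grid = np.linspace(0, 30, 200)
        for df in (1, 3, 7):
            p = [chisq_pvalue(x, df) for x in grid]
            assert all(p1 > p2 for p1, p2 in zip(p, p[1:]))


class TestDiffTable:
    def test_extreme_contig_flagged_up_in_susceptible(self):
        cat = make_catalogue(
            {"hit": {"R": 0, "S": 12}, "bg": {"R": 500, "S": 500}},
            {"R": "resistant", "S": "susceptible"},
        )
        res = diff_table(cat, Contrast.from_catalogue(cat))
        hit = next(r for r in res if r.contig_id == "hit")
        assert hit.direction == "up_in_susceptible"
        assert hit.significant

    def test_low_count_contigs_excluded(self):
        cat = make_catalogue(
            {"tiny": {"R": 1, "S": 2}, "ok": {"R": 30, "S": 30}},
            {"R": "resistant", "S": "susceptible"},
        )
        res = diff_table(cat, Contrast.from_catalogue(cat), min_count=5)
        assert {r.contig_id for r in res} == {"ok"}

    def test_expected_counts_conserve_observed_total(self, toy_catalogue):
        res = diff_table(toy_catalogue, Contrast.from_catalogue(toy_catalogue), min_count=1)
        for r in res:
            assert r.expected_a + r.expected_b == pytest.approx(
                r.observed_a + r.observed_b, abs=1e-9
            )

    def test_unknown_library_in_contrast_rejected(self, toy_catalogue):
        bad = Contrast(name="bad", condition_a={"LibR"}, condition_b={"Nope"})
        with pytest.raises(ValueError, match="Nope"):
            diff_table(toy_catalogue, bad)

    def test_contrast_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            Contrast(name="x", condition_a={"A"}, condition_b={"A"})
        with pytest.raises(ValueError, match="alpha"):
            Contrast(name="x", condition_a={"A"}, condition_b={"B"}, alpha=1.5)

    def test_bh_adjustment_never_flags_more(self):
        rng = np.random.default_rng(5)
        counts = {}
        for i in range(200):
            t = int(rng.integers(20, 120))
            a = int(rng.binomial(t, 0.5))
            counts[f"c{i}"] = {"R": a, "S": t - a}
        counts["big"] = {"R": 5000, "S": 5000}  # keeps depths balanced
        cat = make_catalogue(counts, {"R": "resistant", "S": "susceptible"})
        contrast = Contrast.from_catalogue(cat)
        raw = diff_table(cat, contrast)
        adj = diff_table(cat, contrast, adjust=True)
        assert sum(r.significant for r in adj) <= sum(r.significant for r in raw)


def _flag_fraction(rng, n_contigs, total_range, fold, alpha=0.05):
    """Simulate independent two-condition contigs at equal depths and flag."""
    lo, hi = total_range
    flags = 0
    tested = 0
    p_b = fold / (1.0 + fold)
    for _ in range(n_contigs):
        t = int(rng.integers(lo, hi + 1))
        b = rng.binomial(t, p_b)
        chi2, df = chisq_gof([t - b, b], [t / 2, t / 2])
        flags += chisq_pvalue(chi2, df) < alpha
        tested += 1
    return flags / tested


class TestCalibrationAndPower:
    def test_power_increases_with_fold_change_and_depth(self, rng):
        rates_by_fold = [
            _flag_fraction(rng, 400, (80, 80), fold) for fold in (1.0, 2.0, 4.0)
        ]
        assert rates_by_fold[0] < rates_by_fold[1] < rates_by_fold[2]
        rates_by_total = [
            _flag_fraction(rng, 400, (t, t), 2.0) for t in (20, 80, 320)
        ]
        assert rates_by_total[0] < rates_by_total[1] < rates_by_total[2]
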