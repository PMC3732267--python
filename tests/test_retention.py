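"""Cohort statistics: C_u, C_max, M/N banding, eGFR correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from uremiq.errors import QuantificationError
from uremiq.retention import (
    band_counts,
    cmax,
    cohort_summary,
    egfr_correlation,
    mn_index,
    retention_band,
    spearman_exact,
    summarize_cohort,
)


def _table(values_by_metabolite, detected=True):
    rows = []
    for name, values in values_by_metabolite.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "patient_id": f"P{i:02d}",
                    "metabolite": name,
                    "conc_uM": v,
                    "detected": detected,
                }
            )
    return pd.DataFrame(rows)


def table2_like_frame(library):
    """Cohort table in which every patient sits exactly at the configured
    cohort mean, so the summary reproduces the library's C_u values."""
    return _table({m.name: [m.cohort_mean] * 2 for m in library.uremic_panel()})


class TestSummary:
    def test_hand_arithmetic(self, library):
        df = _table({"betaine": [1.0, 2.0, 3.0]})
        s = cohort_summary(df, "betaine", library)
        assert s.n_detected == 3
        assert s.c_u == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)  # sample SD, ddof = 1
        assert s.c_max == pytest.approx(4.0)

    def test_identical_patients_have_zero_spread(self, library):
        df = _table({"betaine": [80.0] * 5})
        s = cohort_summary(df, "betaine", library)
        assert s.sd == 0.0
        assert s.c_max == s.c_u

    def test_single_detection_has_no_sd(self, library):
        df = _table({"dimethylamine": [17.0]})
        s = cohort_summary(df, "dimethylamine", library)
        assert s.n_detected == 1
        assert s.c_u == pytest.approx(17.0)
        assert s.sd is None and s.c_max is None

    def test_undetected_rows_excluded_from_mean(self, library):
        df = pd.concat(
            [
                _table({"betaine": [60.0, 80.0]}),
                _table({"betaine": [5.0]}, detected=False),
            ]
        )
        s = cohort_summary(df, "betaine", library)
        assert s.n_detected == 2
        assert s.c_u == pytest.approx(70.0)

    def test_sampling_consistency_across_seeds(self, library):
        """Simulated 10-patient cohorts put the empirical C_u within
        2 SD / sqrt(10) of the configured truth, most of the time."""
        from uremiq.simulate import draw_cohort_samples

        hits, total = 0, 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            patients, _ = draw_cohort_samples(10, 0, rng, library)
            values = np.array([p.true_conc["dimethyl sulphone"] for p in patients])
            truth = library["dimethyl sulphone"].cohort_mean
            sd = library["dimethyl sulphone"].cohort_sd
            hits += abs(values.mean() - truth) <= 2.0 * sd / math.sqrt(10)
            total += 1
        assert hits / total >= 0.9


class TestCmax:
    @pytest.mark.parametrize(
        "c_u, sd, expected",
        [(88.0, 42.0, 172.0), (28.0, 24.0, 76.0), (50.0, 0.0, 50.0)],
    )
    def test_values(self, c_u, sd, expected):
        assert cmax(c_u, sd) == pytest.approx(expected)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            cmax(10.0, -1.0)


class TestMN:
    def test_hippuric_acid_index(self):
        assert round(mn_index(134.0, 3.0), 1) == 44.7

    def test_trimethylamine_oxide_index(self):
        assert round(mn_index(88.0, 38.0), 1) == 2.3

    def test_identity(self):
        assert mn_index(38.0, 38.0) == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            mn_index(10.0, 0.0)

    @given(
        c=st.floats(0.1, 1e4),
        n=st.floats(0.1, 1e3),
        a=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, c, n, a):
        assert mn_index(a * c, a * n) == pytest.approx(mn_index(c, n), rel=1e-9)


class TestBanding:
    def test_boundaries(self):
        assert retention_band(10.5) == "high"
        assert retention_band(10.0) == "moderate"  # boundary 10 is moderate
        assert retention_band(4.0) == "moderate"  # boundary 4 is moderate
        assert retention_band(3.99) == "low"
        assert retention_band(50.0, excluded=True) == "excluded"

    def test_band_counts_partition_panel(self, library):
        df = table2_like_frame(library)
        summaries = [cohort_summary(df, m.name, library) for m in library.uremic_panel()]
        counts = band_counts(summaries)
        assert sum(counts.values()) == 14
        assert counts["excluded"] == 3

    def test_reported_band_distribution(self, library):
        """At the configured cohort means, five solutes exceed tenfold
        retention and four sit in the moderate 4-10 band."""
        df = table2_like_frame(library)
        summaries = [cohort_summary(df, m.name, library) for m in library.uremic_panel()]
        counts = band_counts(summaries)
        assert counts["high"] == 5
        assert counts["moderate"] == 4
        assert counts["low"] == 2

    def test_all_normal_is_all_low(self, library):
        df = _table(
            {
                m.name: [m.normal_conc] * 2
                for m in library.uremic_panel()
                if m.normal_conc and not m.excluded_from_mn
            }
        )
        summaries = [
            cohort_summary(df, m, library) for m in df["metabolite"].unique()
        ]
        counts = band_counts(summaries)
        assert counts["low"] == len(summaries)


def _brute_force_spearman_p(x, y):
    """Independent oracle: enumerate every pairing of the y-ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def corr(a, b):
        a = np.asarray(a) - np.mean(a)
        b = np.asarray(b) - np.mean(b)
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    observed = abs(corr(rx, ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        hits += abs(corr(rx, perm)) >= observed - 1e-12
    return hits / total


class TestSpearman:
    def test_perfect_monotone(self):
        r, p = spearman_exact([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(2.0 / math.factorial(5))

    def test_perfect_inverse(self):
        r, _ = spearman_exact([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        _, p = spearman_exact(x, y)
        assert p == pytest.approx(_brute_force_spearman_p(x, y))

    def test_exact_p_with_ties_matches_oracle(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0, 5.0]  # tied values -> midranks
        y = [2.0, 1.0, 4.0, 3.0, 3.0, 6.0]
        _, p = spearman_exact(x, y)
        assert p == pytest.approx(_brute_force_spearman_p(x, y))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_exact([1, 1, 1, 1], [1, 2, 3, 4])

    def test_large_n_falls_back_to_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        r, p = spearman_exact(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestRegression:
    def test_known_line_recovered(self):
        egfr = np.array([14.0, 18.0, 22.0, 26.0, 30.0, 34.0])
        conc = np.exp(2.0 - 0.05 * egfr)
        res = egfr_correlation(conc, egfr, "dimethyl sulphone")
        assert res.pearson_r_ln == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-0.05, abs=1e-9)
        assert res.intercept == pytest.approx(2.0, abs=1e-7)
        assert res.slope_ci[0] <= res.slope <= res.slope_ci[1]
        assert res.intercept_ci[0] <= res.intercept <= res.intercept_ci[1]

    def test_degenerate_input_rejected(self):
        with pytest.raises(QuantificationError):
            egfr_correlation([2.0, 2.0, 2.0], [10.0, 20.0, 30.0])
        with pytest.raises(ValueError):
            egfr_correlation([1.0, 2.0], [10.0, 20.0])


def test_summarize_cohort_rounding(library):
    """Report rounds concentrations to integer uM and M/N to one decimal."""
    df = table2_like_frame(library)
    report = summarize_cohort(df, library)
    assert len(report) == 14
    hip = report[report["metabolite"] == "hippuric acid"].iloc[0]
    assert hip["C_u_uM"] == 134
    assert hip["MN"] == 44.7
    assert hip["band"] == "high"
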