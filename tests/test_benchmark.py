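"""Pared-mean (ABC) and criterion-based benchmarks, exclusions, shortfall."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actbench import (
    cbb_benchmark,
    exclude_small_hospitals,
    hospital_rates,
    pared_mean_benchmark,
    shortfall,
)
from actbench.errors import ModelError, UndefinedStatisticError
from actbench.variation import RateTable, _binom_ci

from conftest import counts_cohort, make_hospitals, make_patients


def rate_table(spec: list[tuple[str, int, int]]) -> RateTable:
    """Rate table straight from (hospital, n, k) triples."""
    return hospital_rates(counts_cohort(spec))


def oracle_pared_mean(spec, fraction):
    """Independent prefix-search oracle: sort by rate desc (ties: larger n,
    then id), enumerate every prefix, return the shortest one whose size
    reaches fraction * total."""
    rows = sorted(spec, key=lambda t: (-t[2] / t[1], -t[1], t[0]))
    total = sum(n for _, n, _ in rows)
    best = None
    for m in range(1, len(rows) + 1):
        prefix = rows[:m]
        if sum(n for _, n, _ in prefix) >= fraction * total:
            best = prefix
            break
    best = best or rows
    ids = [h for h, _, _ in best]
    n = sum(n for _, n, _ in best)
    k = sum(k for _, _, k in best)
    return ids, k / n


class TestExcludeSmallHospitals:
    def test_threshold_boundary(self):
        rates = rate_table([("A", 9, 5), ("B", 10, 5), ("C", 11, 5)])
        kept, report = exclude_small_hospitals(rates, min_cases=10)
        assert kept.table["hospital_id"].tolist() == ["B", "C"]
        assert report.hospitals_excluded == ["A"]
        assert report.patients_excluded == 9
        assert report.patients_remaining == 21

    def test_min_cases_one_excludes_nothing(self):
        rates = rate_table([("A", 1, 1), ("B", 5, 2)])
        kept, report = exclude_small_hospitals(rates, min_cases=1)
        assert len(kept.table) == 2
        assert report.patients_excluded == 0

    def test_conservation_on_study_cohort(self, study_cohort):
        rates = hospital_rates(study_cohort[0])
        below = rates.table[rates.table["n"] < 10]
        _, report = exclude_small_hospitals(rates, min_cases=10)
        assert report.patients_excluded == int(below["n"].sum())
        assert report.patients_remaining + report.patients_excluded == 2801

    def test_all_excluded_raises(self):
        rates = rate_table([("A", 3, 1), ("B", 4, 2)])
        with pytest.raises(UndefinedStatisticError):
            exclude_small_hospitals(rates, min_cases=10)


FIVE_HOSPITALS = [("A", 20, 18), ("B", 30, 24), ("C", 50, 30), ("D", 60, 36), ("E", 40, 20)]


class TestParedMeanBenchmark:
    def test_five_hospital_hand_example(self):
        # total 200; 10% threshold = 20; top hospital (rate .90, n 20) suffices
        res = pared_mean_benchmark(rate_table(FIVE_HOSPITALS), fraction=0.10)
        assert res.selected_hospitals == ["A"]
        assert res.benchmark_n == 20 and res.benchmark_k == 18
        assert res.benchmark_rate == pytest.approx(0.90)
        assert res.nonbenchmark_rate == pytest.approx(110 / 180, abs=1e-9)

    def test_fraction_one_selects_everything(self):
        rates = rate_table(FIVE_HOSPITALS)
        res = pared_mean_benchmark(rates, fraction=1.0)
        assert len(res.selected_hospitals) == 5
        assert res.benchmark_rate == pytest.approx(rates.pooled_rate)
        assert res.shortfall_percent == pytest.approx(0.0, abs=1e-9)

    def test_benchmark_at_least_nonbenchmark(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            spec = [
                (f"H{i}", int(n), int(k))
                for i, (n, k) in enumerate(
                    zip(
                        rng.integers(10, 120, size=8),
                        rng.random(8),
                    )
                )
            ]
            spec = [(h, n, rng.binomial(n, 0.6)) for h, n, _ in spec]
            res = pared_mean_benchmark(rate_table(spec), fraction=0.2)
            if res.nonbenchmark_n:
                assert res.benchmark_rate >= res.nonbenchmark_rate - 1e-12

    def test_conservation_of_counts(self):
        rates = rate_table(FIVE_HOSPITALS)
        res = pared_mean_benchmark(rates, fraction=0.3)
        assert res.benchmark_n + res.nonbenchmark_n == rates.pooled_n
        assert res.benchmark_k + res.nonbenchmark_k == rates.pooled_k

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("fraction", [0.05, 0.10, 0.25, 0.5])
    def test_matches_exhaustive_prefix_oracle(self, seed, fraction):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 13))
        ns = rng.integers(1, 80, size=m)
        ks = rng.binomial(ns, 0.66)
        spec = [(f"H{i:02d}", int(n), int(k)) for i, (n, k) in enumerate(zip(ns, ks))]
        ids, rate = oracle_pared_mean(spec, fraction)
        res = pared_mean_benchmark(rate_table(spec), fraction=fraction)
        assert res.selected_hospitals == ids
        assert res.benchmark_rate == pytest.approx(rate, abs=1e-12)

    def test_selected_share_may_exceed_fraction(self):
        # stopping rule: first prefix reaching the threshold
        res = pared_mean_benchmark(rate_table(FIVE_HOSPITALS), fraction=0.10)
        assert res.selected_fraction >= 0.10

    def test_adjusted_ranking_requires_table(self):
        with pytest.raises(ValueError):
            pared_mean_benchmark(rate_table(FIVE_HOSPITALS), rank_by="adjusted")


class TestShortfall:
    def test_percentage_scale_examples(self):
        assert shortfall(81, 66) == pytest.approx(18.5, abs=0.05)
        assert shortfall(74, 66) == pytest.approx(10.8, abs=0.05)

    def test_zero_at_equal_rates(self):
        for x in (0.2, 55, 100):
            assert shortfall(x, x) == 0.0

    def test_negative_when_actual_exceeds_benchmark(self):
        assert shortfall(60, 66) < 0

    @settings(derandomize=True, max_examples=50)
    @given(
        b=st.floats(1e-3, 100),
        a1=st.floats(0, 100),
        a2=st.floats(0, 100),
    )
    def test_strictly_decreasing_in_actual(self, b, a1, a2):
        if a1 == a2:
            return
        lo, hi = sorted((a1, a2))
        assert shortfall(b, lo) > shortfall(b, hi)

    def test_zero_benchmark_raises(self):
        with pytest.raises(UndefinedStatisticError):
            shortfall(0, 10)


class TestCbbBenchmark:
    def test_constant_criterion_raises(self):
        cohort = counts_cohort([("A", 20, 10), ("B", 20, 10)])
        with pytest.raises(ModelError):
            cbb_benchmark(cohort, "cancer_centre", bootstrap_reps=0)

    def test_null_factor_benchmark_near_provincial(self, null_cohort):
        cohort, _ = null_cohort
        res = cbb_benchmark(cohort, "cancer_centre", bootstrap_reps=200, seed=1)
        assert res.benchmark_rate == pytest.approx(cohort.treated_rate, abs=0.05)
        assert abs(res.shortfall_percent) < 8

    def test_true_factor_effect_detected(self):
        # criterion hospitals treat at +0.5 log-odds: benchmark > provincial
        rng = np.random.default_rng(5)
        from scipy.special import expit, logit

        rows = []
        for h in range(20):
            flagged = h < 6
            p = expit(logit(0.66) + (0.5 if flagged else 0.0))
            for _ in range(150):
                rows.append({"hospital_id": f"H{h:02d}",
                             "treated": int(rng.random() < p)})
        patients = make_patients(rows)
        hospitals = make_hospitals(
            [f"H{h:02d}" for h in range(20)],
            cancer_centre=[1] * 6 + [0] * 14,
        )
        from actbench import Cohort

        cohort = Cohort(patients, hospitals)
        res = cbb_benchmark(
            cohort, "cancer_centre", covariates=[], bootstrap_reps=200, seed=2
        )
        assert res.benchmark_rate > cohort.treated_rate
        assert res.shortfall_percent > 0
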