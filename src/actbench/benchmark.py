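"""Achievable-benchmark (pared-mean) and criterion-based benchmark rates,
and the shortfall statistic.

The ABC ("achievable benchmarks of care") pared-mean: after removing
hospitals with fewer than 10 study cases, hospitals are ranked by descending
treatment rate and accumulated from the top until the selected hospitals
hold at least 10% of the eligible population; the benchmark rate is the
pooled rate in that subset. The case-mix-adjusted variant ranks and pools
the indirectly standardized rates instead.

Criterion-based benchmarking (CBB) takes the case-mix-standardized rate in
hospitals meeting a predefined optimal-access criterion (e.g. comprehensive
cancer centres) as the benchmark.

Shortfall = (benchmark rate - actual rate) / benchmark rate x 100%, the
relative gap between benchmark and achieved utilization.

Because hospital volumes are finite, the pared-mean selects, in part, the
hospitals that got lucky: under a pure-chance null it exceeds the true rate
in expectation, while the CBB benchmark is centred on it. The
:func:`abc_overestimation_experiment` quantifies that selection bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import casemix
from .cohort import Cohort
from .errors import UndefinedStatisticError
from .generate import GeneratorConfig, generate_cohort
from .variation import RateTable, _binom_ci, hospital_rates


@dataclass
class ExclusionReport:
    """Accounting of the small-hospital exclusion."""

    min_cases: int
    hospitals_excluded: list[str]
    patients_excluded: int
    patients_remaining: int

    def to_dict(self) -> dict:
        return {
            "min_cases": self.min_cases,
            "n_hospitals_excluded": len(self.hospitals_excluded),
            "hospitals_excluded": list(self.hospitals_excluded),
            "patients_excluded": self.patients_excluded,
            "patients_remaining": self.patients_remaining,
        }


def exclude_small_hospitals(
    rates: RateTable, min_cases: int = 10
) -> tuple[RateTable, ExclusionReport]:
    """Remove hospitals with fewer than ``min_cases`` cases from a rate table."""
    tab = rates.table
    keep = tab["n"] >= min_cases
    if not keep.any():
        raise UndefinedStatisticError(
            f"every hospital has < {min_cases} cases; nothing left to benchmark"
        )
    removed = tab[~keep]
    kept = tab[keep].reset_index(drop=True)
    pn, pk = int(kept["n"].sum()), int(kept["k"].sum())
    lo, hi = _binom_ci(pk, pn, rates.ci_method)
    new = RateTable(
        table=kept,
        pooled_n=pn,
        pooled_k=pk,
        pooled_rate=pk / pn,
        pooled_ci=(float(lo), float(hi)),
        ci_method=rates.ci_method,
    )
    report = ExclusionReport(
        min_cases=min_cases,
        hospitals_excluded=list(removed["hospital_id"]),
        patients_excluded=int(removed["n"].sum()),
        patients_remaining=pn,
    )
    return new, report


def shortfall(benchmark_rate: float, actual_rate: float) -> float:
    """%Shortfall = (benchmark - actual) / benchmark x 100.

    Works on any consistent scale (proportions or percentages); negative when
    the actual rate exceeds the benchmark.
    """
    if benchmark_rate <= 0:
        raise UndefinedStatisticError("shortfall undefined for benchmark rate <= 0")
    return (benchmark_rate - actual_rate) / benchmark_rate * 100.0


@dataclass
class BenchmarkResult:
    """A benchmark rate, its comparison population, and the shortfall."""

    method: str  # abc_unadjusted | abc_adjusted | cbb
    selected_hospitals: list[str]
    benchmark_n: int
    benchmark_k: int
    benchmark_rate: float
    benchmark_ci: tuple[float, float]
    nonbenchmark_n: int
    nonbenchmark_k: int
    nonbenchmark_rate: float
    nonbenchmark_ci: tuple[float, float]
    comparison_rate: float
    comparison_basis: str  # "provincial" or "nonbenchmark"
    shortfall_percent: float
    selected_fraction: float = float("nan")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "selected_hospitals": list(self.selected_hospitals),
            "benchmark_n": self.benchmark_n,
            "benchmark_k": self.benchmark_k,
            "benchmark_rate": self.benchmark_rate,
            "benchmark_ci": [float(x) for x in self.benchmark_ci],
            "nonbenchmark_n": self.nonbenchmark_n,
            "nonbenchmark_k": self.nonbenchmark_k,
            "nonbenchmark_rate": self.nonbenchmark_rate,
            "nonbenchmark_ci": [float(x) for x in self.nonbenchmark_ci],
            "comparison_rate": self.comparison_rate,
            "comparison_basis": self.comparison_basis,
            "shortfall_percent": self.shortfall_percent,
            "selected_fraction": self.selected_fraction,
        }
        return d


def pared_mean_benchmark(
    rates: RateTable,
    fraction: float = 0.10,
    rank_by: str = "observed",
    adjusted: "casemix.AdjustedRateTable | None" = None,
    comparison: str = "provincial",
) -> BenchmarkResult:
    """ABC pared-mean benchmark over a (post-exclusion) rate table.

    Hospitals are sorted by descending rate (``rank_by='observed'`` uses the
    raw rates; ``'adjusted'`` requires the matching
    :class:`~actbench.casemix.AdjustedRateTable` and ranks/pools the
    standardized rates, n-weighted). The smallest descending-rank prefix whose
    cumulative size reaches ``fraction`` of the eligible population is
    selected; ties break toward larger hospitals, then lexicographic id. The
    shortfall compares the benchmark with the pooled eligible ("provincial")
    rate by default, or with the non-benchmark rate.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    tab = rates.table.copy()
    if tab.empty:
        raise UndefinedStatisticError("empty rate table")
    if rank_by == "observed":
        tab["_rank_rate"] = tab["rate"]
    elif rank_by == "adjusted":
        if adjusted is None:
            raise ValueError("rank_by='adjusted' requires the adjusted rate table")
        adj = adjusted.table.set_index("hospital_id")["adjusted"]
        missing = set(tab["hospital_id"]) - set(adj.index)
        if missing:
            raise ValueError(f"adjusted rates missing for hospital(s) {sorted(missing)}")
        tab["_rank_rate"] = tab["hospital_id"].map(adj)
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")

    tab = tab.sort_values(
        ["_rank_rate", "n", "hospital_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    total_n = int(tab["n"].sum())
    threshold = fraction * total_n
    cum = tab["n"].cumsum()
    n_sel = int(np.searchsorted(cum.to_numpy(), threshold, side="left") + 1)
    n_sel = min(n_sel, len(tab))
    sel, rest = tab.iloc[:n_sel], tab.iloc[n_sel:]

    bn, bk = int(sel["n"].sum()), int(sel["k"].sum())
    nn, nk = int(rest["n"].sum()), int(rest["k"].sum())
    if rank_by == "adjusted":
        bench_rate = float(np.average(sel["_rank_rate"], weights=sel["n"]))
        draws = adjusted.draws
        if draws is not None:
            idx = {h: i for i, h in enumerate(adjusted.table["hospital_id"])}
            rows = [idx[h] for h in sel["hospital_id"]]
            w = sel["n"].to_numpy(float)
            bench_draws = (w[:, None] * draws[rows]).sum(axis=0) / w.sum()
            bench_ci = tuple(np.nanpercentile(bench_draws, [2.5, 97.5]))
        else:
            bench_ci = (float("nan"), float("nan"))
    else:
        bench_rate = bk / bn
        bench_ci = tuple(map(float, _binom_ci(bk, bn, rates.ci_method)))
    if nn > 0:
        non_rate = nk / nn
        non_ci = tuple(map(float, _binom_ci(nk, nn, rates.ci_method)))
    else:
        non_rate, non_ci = float("nan"), (float("nan"), float("nan"))

    comp_rate = rates.pooled_rate if comparison == "provincial" else non_rate
    return BenchmarkResult(
        method=f"abc_{'adjusted' if rank_by == 'adjusted' else 'unadjusted'}",
        selected_hospitals=list(sel["hospital_id"]),
        benchmark_n=bn,
        benchmark_k=bk,
        benchmark_rate=float(bench_rate),
        benchmark_ci=(float(bench_ci[0]), float(bench_ci[1])),
        nonbenchmark_n=nn,
        nonbenchmark_k=nk,
        nonbenchmark_rate=float(non_rate),
        nonbenchmark_ci=non_ci,
        comparison_rate=float(comp_rate),
        comparison_basis=comparison,
        shortfall_percent=shortfall(bench_rate, comp_rate),
        selected_fraction=bn / total_n,
    )


def cbb_benchmark(
    cohort: Cohort,
    criterion: str = "cancer_centre",
    covariates: list[str] | None = None,
    bootstrap_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> BenchmarkResult:
    """Criterion-based benchmark: the case-mix-standardized rate in hospitals
    meeting the criterion, compared with the provincial rate."""
    effect = casemix.factor_effect(
        cohort, criterion, covariates, bootstrap_reps=bootstrap_reps, seed=seed
    )
    merged = cohort.merged()
    in_group = merged[merged[criterion] == 1]
    out_group = merged[merged[criterion] == 0]
    bn, bk = len(in_group), int(in_group["treated"].sum())
    nn, nk = len(out_group), int(out_group["treated"].sum())
    bench_rate = effect.adjusted_rates[1]
    bench_ci = effect.adjusted_rate_cis[1]
    provincial = cohort.treated_rate
    selected = list(
        cohort.hospitals.loc[cohort.hospitals[criterion] == 1, "hospital_id"]
    )
    return BenchmarkResult(
        method="cbb",
        selected_hospitals=selected,
        benchmark_n=bn,
        benchmark_k=bk,
        benchmark_rate=float(bench_rate),
        benchmark_ci=(float(bench_ci[0]), float(bench_ci[1])),
        nonbenchmark_n=nn,
        nonbenchmark_k=nk,
        nonbenchmark_rate=nk / nn if nn else float("nan"),
        nonbenchmark_ci=tuple(map(float, _binom_ci(nk, nn, "wilson"))) if nn else (float("nan"),) * 2,
        comparison_rate=float(provincial),
        comparison_basis="provincial",
        shortfall_percent=shortfall(bench_rate, provincial),
        selected_fraction=bn / (bn + nn),
    )


def abc_overestimation_experiment(
    config: GeneratorConfig,
    replicates: int = 200,
    seed: int = 0,
    fraction: float = 0.10,
    min_cases: int = 10,
    adjusted: bool = True,
    cbb: bool = True,
    cbb_criterion: str = "cancer_centre",
) -> pd.DataFrame:
    """Selection bias of the pared-mean under repeated sampling.

    For each replicate a cohort is generated from ``config``, the unadjusted
    (and optionally case-mix-adjusted) ABC benchmark and the CBB benchmark
    are computed, and every benchmark is compared with the generator's true
    base rate. Under a pure-chance null (``hospital_sd = 0``) the mean
    unadjusted ABC benchmark exceeds the true rate — the pared-mean picks the
    hospitals whose binomial noise came up high — while the CBB shortfall is
    centred on zero. Returns one row per replicate.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cfg_dict = config.to_dict()
        cfg_dict["seed"] = rep_seed
        cohort, _ = generate_cohort(GeneratorConfig(**cfg_dict))
        rates = hospital_rates(cohort)
        eligible, _report = exclude_small_hospitals(rates, min_cases=min_cases)
        row = {"replicate": i, "provincial_rate": rates.pooled_rate}
        abc = pared_mean_benchmark(eligible, fraction=fraction)
        row["abc_benchmark"] = abc.benchmark_rate
        row["abc_shortfall"] = shortfall(abc.benchmark_rate, config.base_rate)
        if adjusted:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                model = casemix.fit_outcome_model(cohort)
            adj = casemix.adjusted_hospital_rates(cohort, model, bootstrap_reps=0)
            adj_abc = pared_mean_benchmark(
                eligible, fraction=fraction, rank_by="adjusted", adjusted=adj
            )
            row["abc_adjusted_benchmark"] = adj_abc.benchmark_rate
            row["abc_adjusted_shortfall"] = shortfall(
                adj_abc.benchmark_rate, config.base_rate
            )
        if cbb:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res = cbb_benchmark(cohort, cbb_criterion, bootstrap_reps=0)
            row["cbb_benchmark"] = res.benchmark_rate
            row["cbb_shortfall"] = shortfall(res.benchmark_rate, config.base_rate)
        rows.append(row)
    return pd.DataFrame(rows)
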