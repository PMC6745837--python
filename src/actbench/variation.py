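"""Hospital-specific treatment rates and the random/nonrandom decomposition
of their variation.

The coefficient of variation (CV) — the sample standard deviation of the
hospital-specific ACT rates divided by their unweighted mean — summarizes
inter-hospital variation. Because hospitals see finite numbers of patients,
a nonzero CV is expected even when every hospital shares the same underlying
treatment probability. A Monte Carlo simulation quantifies that chance
component: each iteration draws k_h ~ Binomial(n_h, p) per hospital with p
set to the pooled observed rate and the actual hospital volumes, and the CV
of the simulated rates is recorded. The mean of the simulated CVs is the
variation expected from chance alone; the observed CV minus this expectation
is the nonrandom component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort
from .errors import UndefinedStatisticError

_CI_METHODS = {"wilson": "wilson", "wald": "normal"}


def _binom_ci(k, n, method: str = "wilson") -> tuple[np.ndarray, np.ndarray]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method=_CI_METHODS[method])
    return lo, hi


@dataclass
class RateTable:
    """Per-hospital numerator/denominator/rate with CIs, plus the pooled rate.

    ``table`` columns: hospital_id, n, k, rate, ci_low, ci_high.
    """

    table: pd.DataFrame
    pooled_n: int
    pooled_k: int
    pooled_rate: float
    pooled_ci: tuple[float, float]
    ci_method: str = "wilson"

    @property
    def rates(self) -> np.ndarray:
        return self.table["rate"].to_numpy(float)

    @property
    def n_hospitals(self) -> int:
        return len(self.table)


def hospital_rates(
    cohort: Cohort, min_cases: int = 1, ci_method: str = "wilson"
) -> RateTable:
    """Observed ACT rate per hospital (denominator >= ``min_cases``).

    The pooled row is total k over total n across the included hospitals,
    with a binomial CI (Wilson score by default, Wald optional).
    """
    if cohort.n_patients == 0:
        raise UndefinedStatisticError("empty cohort")
    g = (
        cohort.patients.groupby("hospital_id", sort=True)["treated"]
        .agg(n="size", k="sum")
        .reset_index()
    )
    g = g[g["n"] >= min_cases].reset_index(drop=True)
    if g.empty:
        raise UndefinedStatisticError(f"no hospital has >= {min_cases} cases")
    g["rate"] = g["k"] / g["n"]
    lo, hi = _binom_ci(g["k"], g["n"], ci_method)
    g["ci_low"], g["ci_high"] = np.clip(lo, 0, 1), np.clip(hi, 0, 1)
    pn, pk = int(g["n"].sum()), int(g["k"].sum())
    plo, phi = _binom_ci(pk, pn, ci_method)
    return RateTable(
        table=g,
        pooled_n=pn,
        pooled_k=pk,
        pooled_rate=pk / pn,
        pooled_ci=(float(plo), float(phi)),
        ci_method=ci_method,
    )


def coefficient_of_variation(rates: RateTable | np.ndarray) -> float:
    """CV = sample SD (n-1 denominator) / unweighted mean of hospital rates."""
    r = rates.rates if isinstance(rates, RateTable) else np.asarray(rates, float)
    if len(r) < 2:
        raise UndefinedStatisticError("CV requires at least 2 hospitals")
    m = r.mean()
    if m == 0:
        raise UndefinedStatisticError("CV undefined: mean rate is 0")
    return float(r.std(ddof=1) / m)


@dataclass
class CvDecomposition:
    """Observed CV against its Monte Carlo null distribution.

    ``nonrandom_component`` is the raw difference observed minus expected
    (may be negative); ``observed_within_ci`` flags whether the observed CV
    lies inside the 2.5–97.5 percentile band of the simulated null CVs.
    Iterations whose CV is undefined (every simulated count zero) are
    excluded from the distribution and counted in ``n_degenerate``.
    """

    expected_cv: float
    expected_ci: tuple[float, float]
    n_iterations: int
    n_degenerate: int
    simulated_cvs: np.ndarray = field(repr=False)
    observed_cv: float | None = None
    nonrandom_component: float | None = None
    observed_within_ci: bool | None = None

    def to_dict(self) -> dict:
        return {
            "observed_cv": self.observed_cv,
            "expected_cv": self.expected_cv,
            "expected_ci": list(self.expected_ci),
            "nonrandom_component": self.nonrandom_component,
            "observed_within_ci": self.observed_within_ci,
            "n_iterations": self.n_iterations,
            "n_degenerate": self.n_degenerate,
        }


def nonrandom_component(observed_cv: float, expected_cv: float) -> float:
    """Systematic share of rate variation: observed CV minus chance-expected CV."""
    return observed_cv - expected_cv


def simulate_null_cv(
    hospital_ns,
    p: float,
    iterations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> CvDecomposition:
    """Null distribution of the CV under a common treatment probability.

    Each iteration draws independent Binomial(n_h, p) counts with the
    supplied hospital denominators and computes the CV of the resulting
    rates. Returns the defined CVs, their mean (expected CV) and empirical
    95% percentile interval.
    """
    ns = np.asarray(hospital_ns, dtype=np.int64)
    if len(ns) < 2:
        raise UndefinedStatisticError("need at least 2 hospitals")
    if (ns < 1).any():
        raise ValueError("all hospital denominators must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = rng.binomial(ns[None, :], p, size=(iterations, len(ns)))
    rates = k / ns[None, :]
    means = rates.mean(axis=1)
    defined = means > 0
    n_degenerate = int((~defined).sum())
    if defined.sum() == 0:
        raise UndefinedStatisticError("all iterations degenerate (mean rate 0)")
    cvs = rates[defined].std(axis=1, ddof=1) / means[defined]
    lo, hi = np.percentile(cvs, [2.5, 97.5])
    return CvDecomposition(
        expected_cv=float(cvs.mean()),
        expected_ci=(float(lo), float(hi)),
        n_iterations=iterations,
        n_degenerate=n_degenerate,
        simulated_cvs=cvs,
    )


def decompose_variation(
    cohort: Cohort,
    iterations: int = 1000,
    seed: int | np.random.Generator | None = None,
    min_cases: int = 1,
) -> CvDecomposition:
    """Observed CV, chance-expected CV, and their difference for a cohort.

    The null is simulated with p equal to the pooled observed rate and the
    cohort's actual hospital volumes (hospitals with >= ``min_cases`` cases).
    """
    rates = hospital_rates(cohort, min_cases=min_cases)
    observed = coefficient_of_variation(rates)
    null = simulate_null_cv(
        rates.table["n"].to_numpy(), rates.pooled_rate, iterations, seed
    )
    null.observed_cv = observed
    null.nonrandom_component = nonrandom_component(observed, null.expected_cv)
    lo, hi = null.expected_ci
    null.observed_within_ci = bool(lo <= observed <= hi)
    return null
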