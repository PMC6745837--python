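"""Synthetic cohort generator.

Emulates the statistical structure of the Ontario stage III colon cancer
cohort: 72 hospitals, 2801 patients, an overall adjuvant-chemotherapy (ACT)
rate of 66%, published covariate marginals, a logistic outcome model with
configurable covariate effects, and configurable hospital-level random
intercepts. Setting ``hospital_sd = 0`` yields the pure-chance null in which
every hospital shares one underlying treatment probability — the hypothesis
the Monte Carlo variation decomposition tests.

Covariates are drawn independently from their marginals: only marginal
distributions are published for the source cohort, so no correlation
structure is imposed. Hospital volumes are likewise unpublished; the
"study-like" profile is a discretized lognormal rescaled so that the
published aggregates hold (by default 25 hospitals under 10 cases holding
150 patients, with the remaining hospitals sharing 2651).

Randomness uses one master seed with named substreams per stage (sizes,
hospital effects, one per covariate, outcomes) so that, e.g., adding a
covariate does not perturb hospital sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import nbinom

from .cohort import (
    CATEGORY_DOMAINS,
    Cohort,
    HOSPITAL_COLUMNS,
    PATIENT_COLUMNS,
)
from .errors import ConfigurationError

import pandas as pd

# Covariate marginals of the study population (counts over n = 2801).
_MARGINAL_COUNTS: dict[str, dict[str, int]] = {
    "age_group": {"20-49": 207, "50-59": 437, "60-69": 727, "70-79": 872, "80+": 558},
    "sex": {"M": 1462, "F": 1339},
    "ses_quintile": {"1": 595, "2": 648, "3": 590, "4": 509, "5": 453, "unknown": 6},
    "charlson": {"0": 2267, "1": 313, "2+": 221},
    "grade": {"well-moderate": 2141, "poor": 610, "unstated": 50},
    "lvi": {"yes": 1378, "no": 1209, "NA": 214},
    "t_stage": {"T<=1": 43, "T2": 180, "T3": 1854, "T4": 724},
    "n_stage": {"N1": 1663, "N2": 1138},
    "node_harvest": {">=12": 2051, "<12": 744, "unknown": 6},
}

DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    cov: {lvl: cnt / sum(cnts.values()) for lvl, cnt in cnts.items()}
    for cov, cnts in _MARGINAL_COUNTS.items()
}

# Default covariate effects on the log-odds of treatment. Utilization falls
# steeply with age and comorbidity; other covariates are left neutral.
DEFAULT_LOG_ODDS: dict[str, dict[str, float]] = {
    "age_group": {"20-49": 0.0, "50-59": -0.2, "60-69": -0.5, "70-79": -1.3, "80+": -2.6},
    "charlson": {"0": 0.0, "1": -0.4, "2+": -0.8},
}

# Length of stay (days) ~ 1 + NegBin(r, q): mean 8, median 8.
_LOS_R, _LOS_Q = 5.0, 5.0 / 12.0


def _los_pmf(days: np.ndarray) -> np.ndarray:
    """pmf of length of stay on integer days >= 1."""
    return nbinom.pmf(np.asarray(days) - 1, _LOS_R, _LOS_Q)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 72 hospitals, 2801 patients,
    base ACT rate 0.66, published covariate marginals, age and Charlson
    gradients, and no systematic hospital variation (``hospital_sd = 0``).
    """

    n_hospitals: int = 72
    n_patients: int = 2801
    base_rate: float = 0.66
    hospital_size_profile: str | Sequence[float] = "study-like"
    #: study-like profile: this many hospitals fall below ``small_threshold``
    #: cases and together hold ``small_patients`` patients
    small_hospitals: int = 25
    small_patients: int = 150
    small_threshold: int = 10
    covariate_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    covariate_log_odds: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LOG_ODDS.items()}
    )
    #: continuous log-odds effect of each day of hospital stay
    los_log_odds_per_day: float = 0.0
    hospital_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_hospitals < 1 or self.n_patients < 1:
            raise ConfigurationError("n_hospitals and n_patients must be positive")
        if self.n_hospitals > self.n_patients:
            raise ConfigurationError(
                f"infeasible size profile: {self.n_hospitals} hospitals > "
                f"{self.n_patients} patients"
            )
        if not 0.0 <= self.base_rate <= 1.0:
            raise ConfigurationError("base_rate must be a probability")
        if self.hospital_sd < 0:
            raise ConfigurationError("hospital_sd must be non-negative")
        for cov, marg in self.covariate_marginals.items():
            if cov not in CATEGORY_DOMAINS:
                raise ConfigurationError(f"unknown covariate {cov!r}")
            levels = set(marg)
            if levels != set(CATEGORY_DOMAINS[cov]):
                raise ConfigurationError(
                    f"marginals for {cov!r} must cover exactly {CATEGORY_DOMAINS[cov]}"
                )
            probs = np.array(list(marg.values()), float)
            if (probs < 0).any() or (probs > 1).any():
                raise ConfigurationError(f"marginals for {cov!r} outside [0,1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"marginals for {cov!r} do not sum to 1")
        for cov, eff in self.covariate_log_odds.items():
            if cov not in CATEGORY_DOMAINS:
                raise ConfigurationError(f"unknown covariate {cov!r} in effects")
            extra = set(eff) - set(CATEGORY_DOMAINS[cov])
            if extra:
                raise ConfigurationError(f"unknown level(s) {sorted(extra)} for {cov!r}")
        if isinstance(self.hospital_size_profile, str):
            if self.hospital_size_profile not in ("study-like", "uniform"):
                raise ConfigurationError(
                    f"unknown size profile {self.hospital_size_profile!r}"
                )
            if self.hospital_size_profile == "study-like":
                ns, np_small = self.small_hospitals, self.small_patients
                n_large = self.n_hospitals - ns
                large_pat = self.n_patients - np_small
                if ns > 0 and not (ns <= np_small <= ns * (self.small_threshold - 1)):
                    raise ConfigurationError(
                        "small_patients incompatible with small_hospitals and threshold"
                    )
                if n_large < 0 or large_pat < n_large * self.small_threshold:
                    raise ConfigurationError(
                        "not enough patients for every large hospital to reach the "
                        "small-hospital threshold"
                    )
        else:
            if len(self.hospital_size_profile) != self.n_hospitals:
                raise ConfigurationError("custom weights length must equal n_hospitals")

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["hospital_size_profile"], str):
            d["hospital_size_profile"] = list(map(float, d["hospital_size_profile"]))
        return d


@dataclass
class TruthRecord:
    """Ground truth stored alongside a generated cohort for recovery tests."""

    intercept: float
    covariate_log_odds: dict[str, dict[str, float]]
    los_log_odds_per_day: float
    hospital_sd: float
    hospital_effects: dict[str, float]
    hospital_sizes: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


def _allocate(weights: np.ndarray, total: int, low: int, high: int | None) -> np.ndarray:
    """Integer allocation proportional to weights, each in [low, high], summing to total."""
    n = len(weights)
    hi = total if high is None else high
    if n * low > total or n * hi < total:
        raise ConfigurationError("infeasible integer allocation")
    w = np.asarray(weights, float)
    w = w / w.sum()
    x = np.clip(np.round(w * total).astype(int), low, hi)
    # repair the sum, preferring the largest (or smallest) cells
    order = np.argsort(-w)
    i = 0
    while x.sum() != total:
        j = order[i % n]
        if x.sum() < total and x[j] < hi:
            x[j] += 1
        elif x.sum() > total and x[j] > low:
            x[j] -= 1
        i += 1
    return x


def hospital_sizes(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw hospital case counts per the configured profile (sums to n_patients)."""
    H, N = config.n_hospitals, config.n_patients
    prof = config.hospital_size_profile
    if isinstance(prof, str) and prof == "uniform":
        return _allocate(np.ones(H), N, 1, None)
    if not isinstance(prof, str):
        return _allocate(np.asarray(prof, float), N, 1, None)
    # study-like: heavy-tailed lognormal, rescaled in two strata so a known
    # number of hospitals sit below the small-case threshold
    raw = np.sort(rng.lognormal(mean=0.0, sigma=1.0, size=H))
    ns = min(config.small_hospitals, H - 1) if config.small_patients else 0
    sizes = np.empty(H, dtype=int)
    if ns > 0:
        sizes[:ns] = _allocate(
            raw[:ns], config.small_patients, 1, config.small_threshold - 1
        )
        sizes[ns:] = _allocate(
            raw[ns:], N - config.small_patients, config.small_threshold, None
        )
    else:
        sizes = _allocate(raw, N, 1, None)
    return sizes


def _effect_offsets(config: GeneratorConfig):
    """Distribution of the covariate part of the linear predictor.

    Enumerates the joint support of the covariates with nonzero effects
    (covariates are independent, so the rest integrate out exactly). Returns
    (offsets, probabilities).
    """
    offsets = np.array([0.0])
    probs = np.array([1.0])

    def _extend(vals: np.ndarray, ps: np.ndarray):
        nonlocal offsets, probs
        offsets = (offsets[:, None] + vals[None, :]).ravel()
        probs = (probs[:, None] * ps[None, :]).ravel()

    for cov, eff in config.covariate_log_odds.items():
        if not any(v != 0.0 for v in eff.values()):
            continue
        marg = config.covariate_marginals[cov]
        levels = CATEGORY_DOMAINS[cov]
        _extend(
            np.array([eff.get(l, 0.0) for l in levels]),
            np.array([marg[l] for l in levels]),
        )
    if config.los_log_odds_per_day != 0.0:
        days = np.arange(1, 400)
        pm = _los_pmf(days)
        keep = pm > 1e-14
        _extend(config.los_log_odds_per_day * days[keep], pm[keep] / pm[keep].sum())
    return offsets, probs


def calibrate_intercept(config: GeneratorConfig) -> float:
    """Log-odds intercept making the marginal treated fraction equal base_rate.

    The marginal mean of the model-implied probabilities over the covariate
    distribution is monotone in the intercept, so a bracketed root-find
    converges to within 1e-6. Degenerate base rates 0 and 1 map to +/-inf.
    """
    config.validate()
    if config.base_rate >= 1.0:
        return np.inf
    if config.base_rate <= 0.0:
        return -np.inf
    offsets, probs = _effect_offsets(config)
    if len(offsets) == 1:  # no active effects: closed form
        return float(logit(config.base_rate) - offsets[0])

    def marginal(a: float) -> float:
        return float(np.sum(probs * expit(a + offsets)) - config.base_rate)

    return float(brentq(marginal, -60.0, 60.0, xtol=1e-9))


def _assign_flags(sizes: np.ndarray, config: GeneratorConfig) -> pd.DataFrame:
    """Hospital attribute flags: the largest hospitals are the teaching
    hospitals, comprehensive cancer centres and on-site oncology sites,
    mirroring the study's counts (14 / 13 / 32 of 72), scaled to n_hospitals."""
    H = len(sizes)
    order = np.argsort(-sizes, kind="stable")  # largest first
    counts = {
        "teaching": max(1, round(H * 14 / 72)) if H > 1 else 0,
        "cancer_centre": max(1, round(H * 13 / 72)) if H > 1 else 0,
        "medonc_onsite": max(1, round(H * 32 / 72)) if H > 1 else 0,
    }
    flags = pd.DataFrame(0, index=range(H), columns=list(counts), dtype=int)
    for col, k in counts.items():
        flags.loc[order[:k], col] = 1
    return flags


def generate_cohort(config: GeneratorConfig | None = None) -> tuple[Cohort, TruthRecord]:
    """Generate a synthetic cohort and the ground truth that produced it.

    Deterministic in ``config.seed``: identical configs yield identical
    cohorts, byte for byte once written.
    """
    config = config or GeneratorConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(3 + len(CATEGORY_DOMAINS) + 1)
    rng_sizes = np.random.default_rng(streams[0])
    rng_effects = np.random.default_rng(streams[1])
    rng_outcomes = np.random.default_rng(streams[2])
    cov_rngs = {
        cov: np.random.default_rng(s)
        for cov, s in zip(sorted(CATEGORY_DOMAINS), streams[3:])
    }
    rng_los = np.random.default_rng(streams[3 + len(CATEGORY_DOMAINS)])

    sizes = hospital_sizes(config, rng_sizes)
    H = config.n_hospitals
    width = max(3, len(str(H)))
    hosp_ids = np.array([f"H{i+1:0{width}d}" for i in range(H)])
    hosp_of_patient = np.repeat(np.arange(H), sizes)
    N = config.n_patients

    data: dict[str, np.ndarray] = {}
    pw = max(5, len(str(N)))
    data["patient_id"] = np.array([f"P{i+1:0{pw}d}" for i in range(N)])
    data["hospital_id"] = hosp_ids[hosp_of_patient]
    for cov in sorted(CATEGORY_DOMAINS):
        levels = CATEGORY_DOMAINS[cov]
        marg = config.covariate_marginals.get(cov, DEFAULT_MARGINALS[cov])
        p = np.array([marg[l] for l in levels], float)
        data[cov] = cov_rngs[cov].choice(levels, size=N, p=p / p.sum())
    los = rng_los.negative_binomial(_LOS_R, _LOS_Q, size=N) + 1
    data["length_of_stay"] = los.astype(np.int64)

    intercept = calibrate_intercept(config)
    eta = np.full(N, intercept, dtype=float)
    for cov, eff in config.covariate_log_odds.items():
        lut = {l: eff.get(l, 0.0) for l in CATEGORY_DOMAINS[cov]}
        eta += pd.Series(data[cov]).map(lut).to_numpy(float)
    eta += config.los_log_odds_per_day * los
    u = rng_effects.normal(0.0, config.hospital_sd, size=H) if config.hospital_sd else np.zeros(H)
    eta += u[hosp_of_patient]
    p = expit(eta)
    data["treated"] = (rng_outcomes.random(N) < p).astype(np.int64)

    patients = pd.DataFrame(data)[PATIENT_COLUMNS]
    hospitals = _assign_flags(sizes, config)
    hospitals.insert(0, "hospital_id", hosp_ids)
    cohort = Cohort(patients, hospitals[HOSPITAL_COLUMNS])
    truth = TruthRecord(
        intercept=float(intercept),
        covariate_log_odds={k: dict(v) for k, v in config.covariate_log_odds.items()},
        los_log_odds_per_day=config.los_log_odds_per_day,
        hospital_sd=config.hospital_sd,
        hospital_effects={h: float(v) for h, v in zip(hosp_ids, u)},
        hospital_sizes={h: int(s) for h, s in zip(hosp_ids, sizes)},
    )
    return cohort, truth


def null_config(**overrides) -> GeneratorConfig:
    """A pure-chance configuration: no covariate effects, no hospital effects.

    Every patient shares one treatment probability, so per-hospital counts
    are exactly binomial — the null the Monte Carlo CV decomposition assumes.
    """
    overrides.setdefault("covariate_log_odds", {})
    overrides.setdefault("hospital_sd", 0.0)
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg
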