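"""Case-mix adjustment: outcome model, standardized hospital rates, factor
effects, and the multilevel intraclass correlation.

The outcome model is a maximum-likelihood logistic regression of the
treatment indicator on the patient- and disease-level covariates (age, sex,
socioeconomic quintile, Charlson comorbidity, length of stay, T stage,
N stage, lymphovascular invasion, histological grade), reference-coded.

Hospital rates are adjusted by indirect standardization: each hospital's
expected rate is the mean model-predicted probability over its own patients,
and adjusted = (observed / expected) x pooled rate. Uncertainty comes from a
parametric bootstrap in which (i) coefficients are redrawn from the fitted
model's asymptotic normal and (ii) patient outcomes are redrawn from the
implied probabilities; percentile intervals are reported per hospital.

System-level factor effects (teaching hospital, comprehensive cancer centre,
on-site medical oncology) are reported as unadjusted risk ratios and as
case-mix-adjusted rates/risk ratios via marginal standardization: the mean
predicted probability over the full cohort with the factor set to each level,
from one logistic model containing the factor plus the covariates.

The multilevel model is a random-intercept logistic regression (hospital
intercepts ~ N(0, sigma_u^2)) fitted by adaptive-free Gauss-Hermite
quadrature of the marginal likelihood; the ICC on the latent logistic scale
is sigma_u^2 / (sigma_u^2 + pi^2/3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .cohort import CATEGORY_DOMAINS, Cohort
from .errors import ModelError, SeparationError

#: covariates of the adjusted models (node harvest is not in the model)
DEFAULT_COVARIATES = [
    "age_group",
    "sex",
    "ses_quintile",
    "charlson",
    "length_of_stay",
    "t_stage",
    "n_stage",
    "lvi",
    "grade",
]

#: reference level of each categorical covariate
REFERENCE_LEVELS = {
    "age_group": "20-49",
    "sex": "F",
    "ses_quintile": "1",
    "charlson": "0",
    "t_stage": "T3",
    "n_stage": "N1",
    "grade": "well-moderate",
    "lvi": "no",
}


@dataclass
class CovariateSpec:
    """Frozen encoding of a design: covariate list, references, observed levels."""

    categorical: list[str]
    numeric: list[str]
    reference: dict[str, str]
    levels: dict[str, list[str]]  # non-reference levels encoded, per categorical
    ses_unknown: str = "drop"

    @property
    def column_names(self) -> list[str]:
        cols = ["const"]
        for cov in self.categorical:
            cols += [f"{cov}[{lvl}]" for lvl in self.levels[cov]]
        cols += list(self.numeric)
        return cols


def _split_covariates(covariates: list[str], df: pd.DataFrame):
    categorical, numeric = [], []
    for cov in covariates:
        if cov in CATEGORY_DOMAINS:
            categorical.append(cov)
        elif cov in df.columns:
            numeric.append(cov)
        else:
            raise ModelError(f"unknown covariate {cov!r}")
    return categorical, numeric


def _prepare(df: pd.DataFrame, spec: CovariateSpec, warn: bool = False) -> pd.DataFrame:
    """Apply the SES-unknown policy; returns the analysis rows."""
    if spec.ses_unknown == "drop" and "ses_quintile" in spec.categorical:
        mask = df["ses_quintile"].astype(str) == "unknown"
        n = int(mask.sum())
        if n:
            if warn:
                warnings.warn(
                    f"dropping {n} patient(s) with unknown SES from the adjusted model",
                    stacklevel=3,
                )
            df = df[~mask]
    return df.reset_index(drop=True)


def build_spec(
    df: pd.DataFrame, covariates: list[str] | None, ses_unknown: str = "drop"
) -> CovariateSpec:
    covariates = DEFAULT_COVARIATES if covariates is None else list(covariates)
    categorical, numeric = _split_covariates(covariates, df)
    spec = CovariateSpec(categorical, numeric, {}, {}, ses_unknown)
    work = _prepare(df, spec)
    for cov in categorical:
        present = [l for l in CATEGORY_DOMAINS[cov] if (work[cov] == l).any()]
        if not present:
            raise ModelError(f"covariate {cov!r} has no observed levels")
        ref = REFERENCE_LEVELS.get(cov, present[0])
        if ref not in present:
            ref = present[0]
        spec.reference[cov] = ref
        spec.levels[cov] = [l for l in present if l != ref]
    return spec


def design_matrix(df: pd.DataFrame, spec: CovariateSpec) -> np.ndarray:
    """Reference-coded design matrix (with intercept) for prepared rows."""
    n = len(df)
    cols = [np.ones(n)]
    for cov in spec.categorical:
        vals = df[cov].astype(str).to_numpy()
        for lvl in spec.levels[cov]:
            cols.append((vals == lvl).astype(float))
    for cov in spec.numeric:
        cols.append(df[cov].to_numpy(float))
    return np.column_stack(cols)


def _check_separation(df: pd.DataFrame, spec: CovariateSpec, y: np.ndarray) -> None:
    for cov in spec.categorical:
        vals = df[cov].astype(str).to_numpy()
        for lvl in spec.levels[cov] + [spec.reference[cov]]:
            sub = y[vals == lvl]
            if len(sub) and (sub.min() == 1 or sub.max() == 0):
                raise SeparationError(
                    f"level {lvl!r} of {cov!r} perfectly predicts treatment "
                    f"({len(sub)} rows, all treated={int(sub[0])})",
                    covariate=cov,
                )


@dataclass
class OutcomeModel:
    """A fitted logistic outcome model with its design specification."""

    spec: CovariateSpec
    params: np.ndarray
    cov_params: np.ndarray
    column_names: list[str]
    converged: bool
    loglik: float
    n_obs: int

    def prepare(self, df: pd.DataFrame) -> pd.DataFrame:
        return _prepare(df, self.spec)

    def design(self, df: pd.DataFrame) -> np.ndarray:
        return design_matrix(df, self.spec)

    def predict(self, df: pd.DataFrame, params: np.ndarray | None = None) -> np.ndarray:
        """Predicted treatment probabilities for prepared rows."""
        X = self.design(df)
        return expit(X @ (self.params if params is None else params))

    def sample_params(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Coefficient draws from the asymptotic normal N(beta_hat, V_hat)."""
        return rng.multivariate_normal(self.params, self.cov_params, size=size)

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_params))
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "or": np.exp(self.params),
                "ci_low": np.exp(self.params - 1.96 * se),
                "ci_high": np.exp(self.params + 1.96 * se),
            },
            index=self.column_names,
        )


def fit_outcome_model(
    cohort: Cohort | pd.DataFrame,
    covariates: list[str] | None = None,
    ses_unknown: str = "drop",
) -> OutcomeModel:
    """Maximum-likelihood logistic regression of treatment on covariates.

    ``covariates`` may be an empty list (intercept-only model). Raises
    :class:`SeparationError` when a covariate level perfectly predicts the
    outcome and :class:`ModelError` on singular designs or non-convergence.
    """
    df = cohort.patients if isinstance(cohort, Cohort) else cohort
    spec = build_spec(df, covariates, ses_unknown)
    work = _prepare(df, spec, warn=True)
    y = work["treated"].to_numpy(float)
    if y.min() == y.max():
        raise ModelError("outcome is constant: need at least 1 event and 1 non-event")
    _check_separation(work, spec, y)
    X = design_matrix(work, spec)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        cov = np.asarray(res.cov_params())
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"singular design matrix: {exc}") from exc
    except Exception as exc:  # statsmodels separation / numerical failures
        raise ModelError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ModelError("logistic fit did not converge")
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(cov)):
        raise ModelError("logistic fit produced non-finite estimates")
    return OutcomeModel(
        spec=spec,
        params=np.asarray(res.params, float),
        cov_params=cov,
        column_names=spec.column_names,
        converged=True,
        loglik=float(res.llf),
        n_obs=len(work),
    )


# ---------------------------------------------------------------------------
# indirect standardization of hospital rates
# ---------------------------------------------------------------------------


def indirect_standardize(observed, expected, pooled):
    """Indirectly standardized rate: (observed / expected) x pooled."""
    return observed / expected * pooled


@dataclass
class AdjustedRateTable:
    """Observed, expected and case-mix-adjusted rate per hospital.

    ``table`` columns: hospital_id, n, k, observed, expected, adjusted,
    ci_low, ci_high. ``draws`` holds the bootstrap adjusted-rate draws
    (hospitals x reps) for downstream interval construction.
    """

    table: pd.DataFrame
    pooled_rate: float
    bootstrap_reps: int
    draws: np.ndarray | None = field(default=None, repr=False)


def adjusted_hospital_rates(
    cohort: Cohort,
    model: OutcomeModel,
    bootstrap_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> AdjustedRateTable:
    """Indirectly standardized hospital rates with parametric-bootstrap CIs.

    adjusted_h = (observed_h / expected_h) x pooled rate, where expected_h is
    the mean model-predicted probability over hospital h's own patients. Each
    bootstrap replicate redraws coefficients from the model's asymptotic
    normal and patient outcomes from the implied probabilities — the case-mix
    probabilities shifted by a per-hospital log-odds offset calibrated so the
    implied hospital mean reproduces the observed rate (with a 0.5/1
    continuity correction at the boundaries) — then recomputes every adjusted
    rate; CIs are the 2.5/97.5 percentiles.
    """
    df = model.prepare(cohort.patients)
    y = df["treated"].to_numpy(float)
    X = model.design(df)
    hosp = df["hospital_id"].to_numpy()
    ids, codes = np.unique(hosp, return_inverse=True)
    H = len(ids)
    M = np.zeros((H, len(df)))
    M[codes, np.arange(len(df))] = 1.0
    n_h = M.sum(axis=1)

    p_hat = expit(X @ model.params)
    observed = (M @ y) / n_h
    expected = (M @ p_hat) / n_h
    if (expected <= 0).any():
        bad = ids[expected <= 0]
        raise ModelError(f"expected rate is 0 for hospital(s) {list(bad)}")
    pooled = y.mean()
    adjusted = indirect_standardize(observed, expected, pooled)

    ci_low = np.full(H, np.nan)
    ci_high = np.full(H, np.nan)
    draws = None
    if bootstrap_reps > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        eta = X @ model.params
        offsets = _hospital_offsets(eta, codes, n_h, M @ y)
        betas = model.sample_params(rng, bootstrap_reps)  # (B, p)
        P = expit(X @ betas.T)  # (n, B): case-mix probabilities
        Q = expit((X @ betas.T) + offsets[codes][:, None])  # outcome probabilities
        Y = (rng.random(Q.shape) < Q).astype(float)
        obs_b = (M @ Y) / n_h[:, None]
        exp_b = (M @ P) / n_h[:, None]
        pooled_b = Y.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            draws = obs_b / exp_b * pooled_b[None, :]
        ci_low, ci_high = np.nanpercentile(draws, [2.5, 97.5], axis=1)

    table = pd.DataFrame(
        {
            "hospital_id": ids,
            "n": n_h.astype(int),
            "k": (M @ y).astype(int),
            "observed": observed,
            "expected": expected,
            "adjusted": adjusted,
            "ci_low": ci_low,
            "ci_high": ci_high,
        }
    )
    return AdjustedRateTable(
        table=table, pooled_rate=float(pooled), bootstrap_reps=bootstrap_reps, draws=draws
    )


def _hospital_offsets(
    eta: np.ndarray, codes: np.ndarray, n_h: np.ndarray, k_h: np.ndarray
) -> np.ndarray:
    """Per-hospital log-odds offsets d_h so that the mean of
    expit(eta_i + d_h) over hospital h's patients equals its observed rate.

    Boundary rates use the (k + 0.5)/(n + 1) continuity correction so the
    offset stays finite. Solved by bisection (the mean is monotone in d)."""
    H = len(n_h)
    target = (k_h + 0.5) / (n_h + 1)
    target = np.where((k_h > 0) & (k_h < n_h), k_h / n_h, target)
    lo = np.full(H, -30.0)
    hi = np.full(H, 30.0)
    for _ in range(60):
        mid = (lo + hi) / 2
        m = np.bincount(codes, weights=expit(eta + mid[codes]), minlength=H) / n_h
        too_low = m < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# system-level factor effects (marginal standardization)
# ---------------------------------------------------------------------------


@dataclass
class FactorEffect:
    """Unadjusted and case-mix-standardized effect of a binary hospital factor."""

    factor: str
    n_by_level: dict[int, int]
    unadjusted_rates: dict[int, float]
    unadjusted_rr: float
    unadjusted_rr_ci: tuple[float, float]
    adjusted_rates: dict[int, float]
    adjusted_rate_cis: dict[int, tuple[float, float]]
    adjusted_rr: float
    adjusted_rr_ci: tuple[float, float]
    #: bootstrap draws of the standardized rate at factor level 1
    benchmark_draws: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "n_by_level": {str(k): v for k, v in self.n_by_level.items()},
            "unadjusted_rates": {str(k): v for k, v in self.unadjusted_rates.items()},
            "unadjusted_rr": self.unadjusted_rr,
            "unadjusted_rr_ci": list(self.unadjusted_rr_ci),
            "adjusted_rates": {str(k): v for k, v in self.adjusted_rates.items()},
            "adjusted_rr": self.adjusted_rr,
            "adjusted_rr_ci": list(self.adjusted_rr_ci),
        }


def factor_effect(
    cohort: Cohort,
    factor: str,
    covariates: list[str] | None = None,
    bootstrap_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    ses_unknown: str = "drop",
) -> FactorEffect:
    """Effect of a binary hospital attribute on treatment.

    Unadjusted RR = rate(level 1) / rate(level 0) with a Katz log-scale CI.
    Adjusted rates come from marginal standardization: the mean predicted
    probability over the full cohort with the factor set to each level, from
    a logistic model of factor + covariates; the adjusted RR is their ratio,
    with percentile CIs from a parametric bootstrap on the coefficients.
    With an empty covariate list the standardized rates equal the observed
    level rates and the adjusted RR reduces to the unadjusted RR.
    """
    merged = cohort.merged()
    if factor not in merged.columns:
        raise ModelError(f"unknown hospital factor {factor!r}")
    fvals = merged[factor].to_numpy()
    if len(np.unique(fvals)) < 2:
        raise ModelError(f"factor {factor!r} is constant across the cohort")

    k1 = int(merged.loc[merged[factor] == 1, "treated"].sum())
    n1 = int((merged[factor] == 1).sum())
    k0 = int(merged.loc[merged[factor] == 0, "treated"].sum())
    n0 = int((merged[factor] == 0).sum())
    r1, r0 = k1 / n1, k0 / n0
    rr = r1 / r0
    se_log = np.sqrt((1 - r1) / k1 + (1 - r0) / k0)
    rr_ci = (rr * np.exp(-1.96 * se_log), rr * np.exp(1.96 * se_log))

    covariates = DEFAULT_COVARIATES if covariates is None else list(covariates)
    model = fit_outcome_model(merged, covariates + [factor], ses_unknown=ses_unknown)
    work = model.prepare(merged)
    g, X_level = {}, {}
    for level in (0, 1):
        counter = work.copy()
        counter[factor] = level
        X_level[level] = model.design(counter)
        g[level] = float(expit(X_level[level] @ model.params).mean())
    adj_rr = g[1] / g[0]

    adj_cis = {0: (np.nan, np.nan), 1: (np.nan, np.nan)}
    adj_rr_ci = (np.nan, np.nan)
    draws1 = None
    if bootstrap_reps > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        betas = model.sample_params(rng, bootstrap_reps)
        g_draws = {
            level: expit(X_level[level] @ betas.T).mean(axis=0) for level in (0, 1)
        }
        for level in (0, 1):
            adj_cis[level] = tuple(np.percentile(g_draws[level], [2.5, 97.5]))
        rr_draws = g_draws[1] / g_draws[0]
        adj_rr_ci = tuple(np.percentile(rr_draws, [2.5, 97.5]))
        draws1 = g_draws[1]

    return FactorEffect(
        factor=factor,
        n_by_level={0: n0, 1: n1},
        unadjusted_rates={0: r0, 1: r1},
        unadjusted_rr=float(rr),
        unadjusted_rr_ci=(float(rr_ci[0]), float(rr_ci[1])),
        adjusted_rates={0: g[0], 1: g[1]},
        adjusted_rate_cis=adj_cis,
        adjusted_rr=float(adj_rr),
        adjusted_rr_ci=tuple(map(float, adj_rr_ci)),
        benchmark_draws=draws1,
    )


# ---------------------------------------------------------------------------
# random-intercept logistic model and ICC
# ---------------------------------------------------------------------------


def _glmm_nll_grad(theta, X, y, group_starts, z, logw):
    """Negative marginal log-likelihood and gradient of the random-intercept
    logit, Gauss-Hermite quadrature with nodes z and log-weights logw.

    theta = [beta, log sigma]; rows of X must be sorted by group and
    ``group_starts`` gives the first row index of each group.
    """
    beta, sigma = theta[:-1], np.exp(theta[-1])
    eta0 = X @ beta
    T = eta0[:, None] + sigma * z[None, :]  # (n, K)
    s = (2.0 * y - 1.0)[:, None]
    ll_ik = -np.logaddexp(0.0, -s * T)
    S = np.add.reduceat(ll_ik, group_starts, axis=0)  # (H, K)
    A = S + logw[None, :]
    ll_h = logsumexp(A, axis=1)
    nll = -float(ll_h.sum())

    P = np.exp(A - ll_h[:, None])  # posterior node weights per group
    W = np.repeat(P, np.diff(np.append(group_starts, len(y))), axis=0)  # (n, K)
    R = W * (y[:, None] - expit(T))
    g_beta = X.T @ R.sum(axis=1)
    g_logsigma = sigma * float((R * z[None, :]).sum())
    return nll, -np.concatenate([g_beta, [g_logsigma]])


@dataclass
class GlmmFit:
    """A fitted random-intercept logistic model."""

    beta: np.ndarray
    sigma: float
    loglik: float
    converged: bool
    cov_theta: np.ndarray | None  # covariance of [beta, log sigma]
    column_names: list[str]
    n_groups: int

    @property
    def sigma2(self) -> float:
        return self.sigma**2

    @property
    def se_log_sigma(self) -> float:
        if self.cov_theta is None:
            return float("nan")
        return float(np.sqrt(self.cov_theta[-1, -1]))

    def sigma2_ci(self) -> tuple[float, float]:
        se = self.se_log_sigma
        # near sigma = 0 the log-scale Wald interval degenerates
        if not np.isfinite(se) or se > 5:
            return (float("nan"), float("nan"))
        ls = np.log(self.sigma)
        return (float(np.exp(2 * (ls - 1.96 * se))), float(np.exp(2 * (ls + 1.96 * se))))


_SIGMA_FLOOR = 1e-4


def fit_random_intercept_logit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 25,
    column_names: list[str] | None = None,
) -> GlmmFit:
    """ML fit of logit P(y=1) = X beta + u_g, u_g ~ N(0, sigma^2), by
    Gauss-Hermite quadrature over the group random intercepts."""
    y = np.asarray(y, float)
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], np.asarray(groups)[order]
    _, idx = np.unique(gs, return_index=True)
    group_starts = np.sort(idx)
    if len(group_starts) < 2:
        raise ModelError("random-intercept model needs at least 2 hospitals")

    x_nodes, w = np.polynomial.hermite.hermgauss(n_quad)
    z = np.sqrt(2.0) * x_nodes
    logw = np.log(w) - 0.5 * np.log(np.pi)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_beta = sm.Logit(ys, Xs).fit(disp=0, maxiter=100).params
    theta0 = np.concatenate([start_beta, [np.log(0.3)]])
    bounds = [(None, None)] * len(start_beta) + [(np.log(_SIGMA_FLOOR), np.log(20.0))]
    res = minimize(
        _glmm_nll_grad,
        theta0,
        args=(Xs, ys, group_starts, z, logw),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if not res.success and grad_norm > 1e-2:
        raise ModelError(
            f"random-intercept fit did not converge: {res.message} "
            f"(|grad|_max = {grad_norm:.3g})"
        )
    theta = res.x
    sigma = float(np.exp(theta[-1]))
    at_floor = sigma <= _SIGMA_FLOOR * (1 + 1e-6)
    cov = None
    if not at_floor:
        Hmat = _fd_hessian(
            lambda t: _glmm_nll_grad(t, Xs, ys, group_starts, z, logw)[1], theta
        )
        try:
            cov = np.linalg.inv(Hmat)
            if np.any(np.diag(cov) < 0):
                cov = None
        except np.linalg.LinAlgError:
            cov = None
    names = column_names or [f"x{i}" for i in range(X.shape[1])]
    return GlmmFit(
        beta=theta[:-1],
        sigma=sigma,
        loglik=-float(res.fun),
        converged=bool(res.success or grad_norm <= 1e-2),
        cov_theta=cov,
        column_names=names,
        n_groups=len(group_starts),
    )


def _fd_hessian(grad_fn, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian from an analytic gradient."""
    p = len(theta)
    H = np.zeros((p, p))
    for j in range(p):
        step = eps * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * step)
    return (H + H.T) / 2


LATENT_VARIANCE = np.pi**2 / 3  # residual variance of the logistic latent scale


@dataclass
class IccResult:
    """Hospital random-intercept variance and latent-scale ICC."""

    sigma2_u: float
    icc: float
    sigma2_ci: tuple[float, float]
    converged: bool
    loglik: float
    n_hospitals: int

    def to_dict(self) -> dict:
        return {
            "sigma2_u": self.sigma2_u,
            "icc": self.icc,
            "sigma2_ci": list(self.sigma2_ci),
            "converged": self.converged,
            "n_hospitals": self.n_hospitals,
        }


def multilevel_icc(
    cohort: Cohort,
    covariates: list[str] | None = None,
    ses_unknown: str = "drop",
    n_quad: int = 25,
) -> IccResult:
    """ICC from a random-intercept multivariable logistic model.

    ICC = sigma_u^2 / (sigma_u^2 + pi^2/3): the share of latent-scale
    variation in treatment propensity attributable to between-hospital
    differences after case-mix adjustment.
    """
    df = cohort.patients
    spec = build_spec(df, covariates, ses_unknown)
    work = _prepare(df, spec)
    y = work["treated"].to_numpy(float)
    if y.min() == y.max():
        raise ModelError("outcome is constant")
    X = design_matrix(work, spec)
    fit = fit_random_intercept_logit(
        X, y, work["hospital_id"].to_numpy(), n_quad=n_quad,
        column_names=spec.column_names,
    )
    s2 = fit.sigma2
    return IccResult(
        sigma2_u=s2,
        icc=s2 / (s2 + LATENT_VARIANCE),
        sigma2_ci=fit.sigma2_ci(),
        converged=fit.converged,
        loglik=fit.loglik,
        n_hospitals=fit.n_groups,
    )
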