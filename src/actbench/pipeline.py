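"""End-to-end pipeline: run selected analysis stages on a cohort and write
a reproducible bundle of tables and JSON artifacts to a run directory.

Artifacts mirror the study's reporting: a cohort characteristics table, a
system-factor table (unadjusted and adjusted rates and risk ratios), the CV
decomposition, benchmark results, a benchmark vs non-benchmark comparison
table, per-hospital scatter data (observed and adjusted, with the pooled
mean and its CI), and ranked-rate data. Every rendered number is read from
a JSON/CSV artifact; the renderer recomputes nothing. A manifest records
the configuration, seed and package version, and a fixed seed makes the
whole bundle byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import benchmark as bm
from . import casemix, variation
from .cohort import Cohort, read_cohort, write_cohort
from .errors import ConfigurationError
from .generate import GeneratorConfig, generate_cohort

log = logging.getLogger("actbench.pipeline")


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("actbench")
    except PackageNotFoundError:
        return "unknown"

ALL_STAGES = ["generate", "rates", "mc-null", "adjust", "factors", "abc", "cbb", "report"]

FACTORS = ["teaching", "cancer_centre", "medonc_onsite"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Exactly one input source: either ``patient_path``/``hospital_path`` or a
    ``generator`` config. ``seed`` drives every stochastic stage through
    named substreams.
    """

    out_dir: str | Path
    patient_path: str | Path | None = None
    hospital_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    iterations: int = 1000
    bootstrap_reps: int = 1000
    fraction: float = 0.10
    min_cases: int = 10
    ci_method: str = "wilson"
    cbb_criterion: str = "cancer_centre"

    def validate(self) -> None:
        have_files = self.patient_path is not None and self.hospital_path is not None
        if have_files == (self.generator is not None):
            raise ConfigurationError(
                "exactly one input source required: cohort files XOR generator config"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        if out_dir is not None:
            raw["out_dir"] = out_dir
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        for k in ("patient_path", "hospital_path"):
            if d[k] is not None:
                d[k] = str(d[k])
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _cohort_summary(cohort: Cohort) -> "pd.DataFrame":
    import pandas as pd
    from .cohort import CATEGORY_DOMAINS

    rows = []
    n = cohort.n_patients
    for cov, levels in CATEGORY_DOMAINS.items():
        for lvl in levels:
            cnt = int((cohort.patients[cov] == lvl).sum())
            rows.append({"characteristic": cov, "level": lvl, "n": cnt,
                         "percent": round(100 * cnt / n)})
    treated = int(cohort.patients["treated"].sum())
    rows.append({"characteristic": "treated", "level": "yes", "n": treated,
                 "percent": round(100 * treated / n)})
    rows.append({"characteristic": "treated", "level": "no", "n": n - treated,
                 "percent": round(100 * (n - treated) / n)})
    rows.append({"characteristic": "length_of_stay", "level": "median",
                 "n": int(cohort.patients["length_of_stay"].median()), "percent": np.nan})
    return pd.DataFrame(rows)


def _benchmark_comparison(cohort: Cohort, selected: list[str]) -> "pd.DataFrame":
    """Covariate distribution by benchmark status with chi-square p-values."""
    import pandas as pd
    from scipy.stats import chi2_contingency

    from .cohort import CATEGORY_DOMAINS

    merged = cohort.patients.copy()
    merged["benchmark"] = merged["hospital_id"].isin(selected)
    rows = []
    for cov in CATEGORY_DOMAINS:
        ct = pd.crosstab(merged[cov], merged["benchmark"])
        if ct.shape[1] == 2 and (ct.to_numpy().sum(axis=1) > 0).all():
            try:
                p = float(chi2_contingency(ct.to_numpy())[1])
            except ValueError:
                p = float("nan")
        else:
            p = float("nan")
        for lvl in ct.index:
            b = int(ct.loc[lvl, True]) if True in ct.columns else 0
            nb = int(ct.loc[lvl, False]) if False in ct.columns else 0
            rows.append({"characteristic": cov, "level": lvl, "benchmark_n": b,
                         "nonbenchmark_n": nb, "p_value": p})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the selected stages in dependency order; return artifact paths.

    Prerequisite computations of selected stages run silently; only the
    artifacts of selected stages are written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    artifacts: dict[str, Path] = {}
    ss = np.random.SeedSequence(config.seed)
    sub = {name: np.random.default_rng(s)
           for name, s in zip(["mc-null", "adjust", "factors", "cbb"], ss.spawn(4))}

    # --- cohort -----------------------------------------------------------
    if config.generator is not None:
        cohort, truth = generate_cohort(config.generator)
        if "generate" in stages:
            write_cohort(cohort, out / "patients.csv", out / "hospitals.csv")
            truth.to_json(out / "truth.json")
            artifacts["patients"] = out / "patients.csv"
            artifacts["hospitals"] = out / "hospitals.csv"
            artifacts["truth"] = out / "truth.json"
    else:
        cohort = read_cohort(config.patient_path, config.hospital_path)
    log.info("stage=cohort patients=%d hospitals=%d", cohort.n_patients, cohort.n_hospitals)

    rates = variation.hospital_rates(cohort, ci_method=config.ci_method)

    if "rates" in stages:
        path = out / "hospital_rates.csv"
        rates.table.to_csv(path, index=False)
        _write_json(out / "pooled_rate.json", {
            "n": rates.pooled_n, "k": rates.pooled_k,
            "rate": rates.pooled_rate, "ci": list(rates.pooled_ci),
        })
        artifacts["hospital_rates"] = path
        artifacts["pooled_rate"] = out / "pooled_rate.json"
        log.info("stage=rates hospitals=%d pooled=%.4f", rates.n_hospitals, rates.pooled_rate)

    if "mc-null" in stages:
        decomp = variation.decompose_variation(
            cohort, iterations=config.iterations, seed=sub["mc-null"]
        )
        _write_json(out / "cv_decomposition.json", decomp.to_dict())
        np.savetxt(out / "simulated_cvs.tsv", decomp.simulated_cvs, fmt="%.6f")
        artifacts["cv_decomposition"] = out / "cv_decomposition.json"
        artifacts["simulated_cvs"] = out / "simulated_cvs.tsv"
        log.info("stage=mc-null observed_cv=%.4f expected_cv=%.4f",
                 decomp.observed_cv, decomp.expected_cv)

    adjusted = None
    if "adjust" in stages:
        model = casemix.fit_outcome_model(cohort)
        adjusted = casemix.adjusted_hospital_rates(
            cohort, model, bootstrap_reps=config.bootstrap_reps, seed=sub["adjust"]
        )
        if "adjust" in stages:
            adjusted.table.to_csv(out / "adjusted_rates.csv", index=False)
            model.summary_frame().to_csv(out / "outcome_model.csv")
            artifacts["adjusted_rates"] = out / "adjusted_rates.csv"
            artifacts["outcome_model"] = out / "outcome_model.csv"
            log.info("stage=adjust hospitals=%d reps=%d",
                     len(adjusted.table), config.bootstrap_reps)

    if "factors" in stages:
        import pandas as pd

        rows = []
        for f in FACTORS:
            eff = casemix.factor_effect(
                cohort, f, bootstrap_reps=config.bootstrap_reps, seed=sub["factors"]
            )
            for level in (0, 1):
                rows.append({
                    "factor": f, "level": level, "n": eff.n_by_level[level],
                    "unadjusted_rate_pct": round(100 * eff.unadjusted_rates[level]),
                    "adjusted_rate_pct": round(100 * eff.adjusted_rates[level]),
                    "unadjusted_rr": eff.unadjusted_rr if level == 1 else 1.0,
                    "unadjusted_rr_ci_low": eff.unadjusted_rr_ci[0] if level == 1 else np.nan,
                    "unadjusted_rr_ci_high": eff.unadjusted_rr_ci[1] if level == 1 else np.nan,
                    "adjusted_rr": eff.adjusted_rr if level == 1 else 1.0,
                    "adjusted_rr_ci_low": eff.adjusted_rr_ci[0] if level == 1 else np.nan,
                    "adjusted_rr_ci_high": eff.adjusted_rr_ci[1] if level == 1 else np.nan,
                })
        pd.DataFrame(rows).to_csv(out / "factor_table.csv", index=False)
        artifacts["factor_table"] = out / "factor_table.csv"
        log.info("stage=factors factors=%d", len(FACTORS))

    abc_res = None
    if "abc" in stages:
        eligible, report = bm.exclude_small_hospitals(rates, min_cases=config.min_cases)
        abc_res = bm.pared_mean_benchmark(eligible, fraction=config.fraction)
        _write_json(out / "abc_benchmark.json", abc_res.to_dict())
        _write_json(out / "exclusions.json", report.to_dict())
        artifacts["abc_benchmark"] = out / "abc_benchmark.json"
        artifacts["exclusions"] = out / "exclusions.json"
        if adjusted is not None:
            adj_abc = bm.pared_mean_benchmark(
                eligible, fraction=config.fraction, rank_by="adjusted", adjusted=adjusted
            )
            _write_json(out / "abc_adjusted_benchmark.json", adj_abc.to_dict())
            artifacts["abc_adjusted_benchmark"] = out / "abc_adjusted_benchmark.json"
        log.info("stage=abc benchmark=%.4f shortfall=%.1f",
                 abc_res.benchmark_rate, abc_res.shortfall_percent)

    if "cbb" in stages:
        cbb_res = bm.cbb_benchmark(
            cohort, config.cbb_criterion, bootstrap_reps=config.bootstrap_reps,
            seed=sub["cbb"],
        )
        _write_json(out / "cbb_benchmark.json", cbb_res.to_dict())
        artifacts["cbb_benchmark"] = out / "cbb_benchmark.json"
        log.info("stage=cbb benchmark=%.4f shortfall=%.1f",
                 cbb_res.benchmark_rate, cbb_res.shortfall_percent)

    if "report" in stages:
        _cohort_summary(cohort).to_csv(out / "cohort_summary.csv", index=False)
        artifacts["cohort_summary"] = out / "cohort_summary.csv"
        scatter = rates.table[["hospital_id", "n", "rate"]].copy()
        scatter["pooled_rate"] = rates.pooled_rate
        scatter["pooled_ci_low"], scatter["pooled_ci_high"] = rates.pooled_ci
        scatter.to_csv(out / "rate_scatter.tsv", sep="\t", index=False)
        artifacts["rate_scatter"] = out / "rate_scatter.tsv"
        if adjusted is not None:
            adj_sc = adjusted.table[["hospital_id", "n", "adjusted"]].copy()
            adj_sc["pooled_rate"] = adjusted.pooled_rate
            adj_sc.to_csv(out / "adjusted_rate_scatter.tsv", sep="\t", index=False)
            artifacts["adjusted_rate_scatter"] = out / "adjusted_rate_scatter.tsv"
        ranked = rates.table.sort_values(
            ["rate", "n", "hospital_id"], ascending=[False, False, True]
        )[["hospital_id", "n", "k", "rate"]]
        ranked.to_csv(out / "ranked_rates.tsv", sep="\t", index=False)
        artifacts["ranked_rates"] = out / "ranked_rates.tsv"
        if abc_res is not None:
            _benchmark_comparison(cohort, abc_res.selected_hospitals).to_csv(
                out / "benchmark_comparison.csv", index=False
            )
            artifacts["benchmark_comparison"] = out / "benchmark_comparison.csv"
        log.info("stage=report artifacts=%d", len(artifacts))

    config_record = config.to_dict()
    config_record.pop("out_dir")  # keep the bundle location-independent
    manifest = {
        "config": config_record,
        "seed": config.seed,
        "version": _pkg_version(),
        "stages_run": sorted(stages),
        "artifacts": {k: str(v.name) for k, v in artifacts.items()},
    }
    _write_json(out / "manifest.json", manifest)
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
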