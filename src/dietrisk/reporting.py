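"""Pipeline orchestration: CSV inputs in, tidy result tables and manifest out.

A run screens every (food, contaminant) dataset, fits the lognormal
concentration model to the eligible ones, simulates intake for every
demographic with a consumption rate for that food, converts intake into
hazard quotients and/or carcinogenic risks, flags threshold exceedances,
runs the Spearman sensitivity analysis on flagged assessments, and writes
the whole thing out as tidy CSVs plus a manifest from which the run can be
reproduced.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .dist_fit import fit_lognormal_mle, substream
from .exposure_mc import (
    BW_LOWER_BOUND_DEFAULT,
    EF_DAYS_DEFAULT,
    IR_GSD_DEFAULT,
    LIFETIME_YEARS_DEFAULT,
    build_profiles,
    load_consumption,
    load_demographics,
    simulate_intake,
)
from .food_data import (
    PERCENTILE_SET,
    eligible_for_assessment,
    read_concentrations,
    substitute_nondetects,
    summary_table,
)
from .risk_metrics import (
    HQ_THRESHOLD,
    R_THRESHOLD,
    carcinogenic_risk,
    hazard_quotient,
    load_toxicity,
    summarize_risk,
)
from .sensitivity import sensitivity_analysis

__all__ = ["RunConfig", "RunOutcome", "EXIT_CLEAN", "EXIT_FAILURE", "EXIT_EXCLUSIONS",
           "run_assessment", "boxplot_export"]

log = logging.getLogger("dietrisk")

EXIT_CLEAN = 0
EXIT_FAILURE = 1
EXIT_EXCLUSIONS = 2


@dataclass(frozen=True)
class RunConfig:
    """Flat, YAML-loadable run configuration; defaults echo into the manifest."""

    n_iter: int = 10000
    seed: int = 12345
    ef_days: float = EF_DAYS_DEFAULT
    at_lifetime_years: float = LIFETIME_YEARS_DEFAULT
    ir_gsd: float = IR_GSD_DEFAULT
    bw_lower_bound_kg: float = BW_LOWER_BOUND_DEFAULT
    percentile_set: tuple[int, ...] = PERCENTILE_SET
    hq_threshold: float = HQ_THRESHOLD
    r_threshold: float = R_THRESHOLD
    force_sensitivity: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        for name in ("ef_days", "at_lifetime_years", "ir_gsd", "hq_threshold",
                     "r_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a flat key-value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "percentile_set" in raw:
            raw["percentile_set"] = tuple(raw["percentile_set"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["percentile_set"] = list(self.percentile_set)
        return d


@dataclass
class RunOutcome:
    """In-memory result of a run, mirrored by the CSVs on disk."""

    summary: pd.DataFrame
    fits: pd.DataFrame
    risk: pd.DataFrame
    sensitivity: pd.DataFrame
    boxplot: pd.DataFrame
    manifest: dict
    results: list = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        if self.manifest["n_excluded"] or self.manifest["warnings"]:
            return EXIT_EXCLUSIONS
        return EXIT_CLEAN


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def boxplot_export(results) -> pd.DataFrame:
    """Boxplot-ready rows: box at P5/P50/P95, whiskers at min and max."""
    rows = [
        {
            "food_id": r.food_id,
            "contaminant_id": r.contaminant_id,
            "demographic": r.demographic,
            "metric": r.metric,
            "min": r.min,
            "p5": r.percentiles[5],
            "p50": r.percentiles[50],
            "p95": r.percentiles[95],
            "max": r.max,
            "threshold": r.threshold,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows,
        columns=["food_id", "contaminant_id", "demographic", "metric",
                 "min", "p5", "p50", "p95", "max", "threshold"],
    )
    return df.sort_values(
        ["food_id", "contaminant_id", "demographic", "metric"], kind="stable"
    ).reset_index(drop=True)


def assess(datasets, consumption, demographics, toxicity, config: RunConfig) -> RunOutcome:
    """Run the full probabilistic assessment over in-memory inputs."""
    verdicts = []
    warnings = []
    fit_rows = []
    risk_rows = []
    sens_rows = []
    results = []

    for ds in sorted(datasets, key=lambda d: (d.food_id, d.contaminant_id)):
        verdict = eligible_for_assessment(ds)
        entry = {
            "food_id": ds.food_id,
            "contaminant_id": ds.contaminant_id,
            "n": ds.n,
            "n_detects": ds.n_detects,
            "eligible": verdict.eligible,
            "reasons": list(verdict.reasons),
            "assessed_demographics": [],
        }
        verdicts.append(entry)
        if not verdict.eligible:
            log.info("excluded %s/%s: %s", ds.food_id, ds.contaminant_id,
                     "; ".join(verdict.reasons))
            continue

        tox = toxicity.get(ds.contaminant_id)
        if tox is None:
            warnings.append(
                f"no toxicity reference for {ds.contaminant_id}; "
                f"{ds.food_id}/{ds.contaminant_id} skipped"
            )
            continue

        values = substitute_nondetects(ds)
        fit = fit_lognormal_mle(values)
        fit_rows.append(
            {"food_id": ds.food_id, "contaminant_id": ds.contaminant_id,
             "mu_log": fit.mu_log, "sigma_log": fit.sigma_log, "n": fit.n}
        )

        metrics = []
        if tox.rfd is not None:
            metrics.append(("HQ", False))
        if tox.sf is not None:
            metrics.append(("R", True))
        for metric, carcinogenic in metrics:
            profiles = build_profiles(
                ds.food_id, consumption, demographics,
                carcinogenic=carcinogenic,
                ef_days=config.ef_days,
                at_lifetime_years=config.at_lifetime_years,
                ir_gsd=config.ir_gsd,
                bw_lower_bound=config.bw_lower_bound_kg,
            )
            for demo, profile in profiles.items():
                rng = substream(config.seed, ds.food_id, ds.contaminant_id,
                                demo, metric)
                draws = simulate_intake(fit, profile, config.n_iter, rng)
                if metric == "HQ":
                    out = hazard_quotient(draws.intake, tox.rfd, ds.contaminant_id)
                else:
                    out = carcinogenic_risk(draws.intake, tox.sf, ds.contaminant_id)
                res = summarize_risk(
                    out, metric,
                    food_id=ds.food_id, contaminant_id=ds.contaminant_id,
                    demographic=demo, seed=config.seed,
                )
                results.append(res)
                if demo not in entry["assessed_demographics"]:
                    entry["assessed_demographics"].append(demo)
                row = {
                    "food_id": ds.food_id, "contaminant_id": ds.contaminant_id,
                    "demographic": demo, "metric": metric,
                    "mean": float(np.mean(out)), "min": res.min,
                }
                row.update({f"p{p}": res.percentiles[p] for p in PERCENTILE_SET})
                row.update({"max": res.max, "threshold": res.threshold,
                            "exceeds_threshold": res.exceeds_threshold,
                            "n_iter": res.n_iter})
                risk_rows.append(row)

                if res.exceeds_threshold or config.force_sensitivity:
                    table = sensitivity_analysis(draws, out)
                    for srow in table.rows:
                        sens_rows.append(
                            {"food_id": ds.food_id,
                             "contaminant_id": ds.contaminant_id,
                             "demographic": demo, "metric": metric,
                             "parameter": srow.parameter, "rho": srow.rho,
                             "p_value": srow.p_value,
                             "significant": srow.significant,
                             "applicable": srow.applicable}
                        )

    n_excluded = sum(1 for v in verdicts if not v["eligible"])
    manifest = {
        "software": {"name": "dietrisk", "version": _version},
        "config": config.to_dict(),
        "seed_derivation": (
            "numpy SeedSequence([seed, crc32(food), crc32(contaminant), "
            "crc32(demographic), crc32(metric)]) per assessment"
        ),
        "assessments": verdicts,
        "n_datasets": len(verdicts),
        "n_excluded": n_excluded,
        "warnings": warnings,
    }
    sens_cols = ["food_id", "contaminant_id", "demographic", "metric",
                 "parameter", "rho", "p_value", "significant", "applicable"]
    return RunOutcome(
        summary=summary_table(datasets),
        fits=pd.DataFrame(fit_rows, columns=["food_id", "contaminant_id",
                                             "mu_log", "sigma_log", "n"]),
        risk=pd.DataFrame(risk_rows),
        sensitivity=pd.DataFrame(sens_rows, columns=sens_cols),
        boxplot=boxplot_export(results),
        manifest=manifest,
        results=results,
    )


def run_assessment(
    concentrations, consumption, demographics, toxicity, config, out_dir,
    seed: int | None = None,
) -> int:
    """File-based entry point; writes result CSVs and a manifest to ``out_dir``.

    Returns 0 for a clean run, 2 when datasets were excluded or warnings
    raised, and 1 on failure.
    """
    out = Path(out_dir)
    try:
        cfg = RunConfig.from_yaml(config) if config else RunConfig()
        if seed is not None:
            cfg = RunConfig(**{**cfg.to_dict(), "seed": int(seed)})
        datasets = read_concentrations(concentrations)
        cons = load_consumption(consumption)
        demo = load_demographics(demographics)
        tox = load_toxicity(toxicity)
        outcome = assess(datasets, cons, demo, tox, cfg)
    except Exception as exc:  # pragma: no cover - exercised via CLI tests
        log.error("run failed: %s", exc)
        print(f"error: {exc}", file=sys.stderr)
        return EXIT_FAILURE

    out.mkdir(parents=True, exist_ok=True)
    outcome.manifest["inputs"] = {
        "concentrations": {"path": str(concentrations), "sha256": _sha256(concentrations)},
        "consumption": {"path": str(consumption), "sha256": _sha256(consumption)},
        "demographics": {"path": str(demographics), "sha256": _sha256(demographics)},
        "toxicity": {"path": str(toxicity), "sha256": _sha256(toxicity)},
    }
    outcome.summary.to_csv(out / "summary_stats.csv", index=False)
    outcome.fits.to_csv(out / "fits.csv", index=False)
    outcome.risk.to_csv(out / "risk.csv", index=False)
    outcome.sensitivity.to_csv(out / "sensitivity.csv", index=False)
    outcome.boxplot.to_csv(out / "boxplot.csv", index=False)
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(outcome.manifest, sort_keys=False)
    )
    return outcome.exit_code
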