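"""Hazard quotients, carcinogenic risks, percentile summaries, threshold flags.

Non-carcinogenic hazard is expressed as the hazard quotient HQ = I / RfD,
the simulated intake divided by the contaminant's reference dose; values
above 1.00 signal potential hazard.  Carcinogenic risk is R = I * SF, the
intake times the oral slope factor, an incremental lifetime cancer
probability compared against the 1.00e-6 de-minimis lifetime attributable
risk.  Both metrics are summarized by their Monte Carlo percentiles and
flagged when the 95th percentile strictly exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .exposure_mc import ExposureProfile
from .food_data import PERCENTILE_SET, percentile

__all__ = [
    "HQ_THRESHOLD",
    "R_THRESHOLD",
    "ToxicityReference",
    "RiskResult",
    "hazard_quotient",
    "carcinogenic_risk",
    "summarize_risk",
    "required_intake_reduction",
    "load_toxicity",
    "default_toxicity",
]

HQ_THRESHOLD = 1.00
R_THRESHOLD = 1.00e-6
THRESHOLDS = {"HQ": HQ_THRESHOLD, "R": R_THRESHOLD}


@dataclass(frozen=True)
class ToxicityReference:
    """Per-contaminant reference dose and/or oral slope factor with provenance."""

    contaminant_id: str
    rfd: float | None = None  # mg/kg/day
    sf: float | None = None  # (mg/kg/day)^-1
    source: str = ""

    def __post_init__(self) -> None:
        if self.rfd is None and self.sf is None:
            raise ValueError(
                f"toxicity reference for {self.contaminant_id} needs an RfD "
                "or a slope factor"
            )
        if self.rfd is not None and self.rfd <= 0:
            raise ValueError(f"RfD for {self.contaminant_id} must be > 0")
        if self.sf is not None and self.sf <= 0:
            raise ValueError(f"slope factor for {self.contaminant_id} must be > 0")


@dataclass(frozen=True)
class RiskResult:
    """Percentile summary of HQ or R draws with the threshold verdict."""

    food_id: str
    contaminant_id: str
    demographic: str
    metric: str  # "HQ" or "R"
    percentiles: Mapping[int, float]
    min: float
    max: float
    threshold: float
    exceeds_threshold: bool
    n_iter: int
    seed: object = None

    @property
    def p95(self) -> float:
        return self.percentiles[95]


def hazard_quotient(intake, rfd: float | None, contaminant_id: str = "") -> np.ndarray:
    """Element-wise HQ = I / RfD."""
    if rfd is None or rfd <= 0:
        raise ValueError(
            f"hazard quotient requires a positive RfD for {contaminant_id or 'contaminant'}"
        )
    return np.asarray(intake, dtype=float) / rfd


def carcinogenic_risk(intake, sf: float | None, contaminant_id: str = "") -> np.ndarray:
    """Element-wise R = I * SF."""
    if sf is None or sf <= 0:
        raise ValueError(
            f"carcinogenic risk requires a positive slope factor for "
            f"{contaminant_id or 'contaminant'}"
        )
    return np.asarray(intake, dtype=float) * sf


def summarize_risk(
    draws,
    metric: str,
    *,
    food_id: str = "",
    contaminant_id: str = "",
    demographic: str = "",
    seed: object = None,
) -> RiskResult:
    """Percentile summary and strict-inequality threshold flag for HQ/R draws."""
    if metric not in THRESHOLDS:
        raise ValueError(f"metric must be one of {sorted(THRESHOLDS)} (got {metric!r})")
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty set of draws")
    pcts = {p: float(v) for p, v in zip(PERCENTILE_SET, percentile(arr, PERCENTILE_SET))}
    threshold = THRESHOLDS[metric]
    return RiskResult(
        food_id=food_id,
        contaminant_id=contaminant_id,
        demographic=demographic,
        metric=metric,
        percentiles=pcts,
        min=float(arr.min()),
        max=float(arr.max()),
        threshold=threshold,
        exceeds_threshold=bool(pcts[95] > threshold),
        n_iter=int(arr.size),
        seed=seed,
    )


def required_intake_reduction(result: RiskResult, profile: ExposureProfile) -> float:
    """Intake-rate reduction (g/day) bringing the 95th-percentile risk to threshold.

    Risk is homogeneous of degree 1 in the intake rate, so scaling the median
    intake rate by threshold/P95 scales every risk percentile the same way;
    the required reduction is ir * (1 - threshold / P95).  Returns 0 when the
    threshold is not exceeded.
    """
    if result.metric != "R":
        raise ValueError("intake reduction is defined for carcinogenic risk results")
    p95 = result.p95
    if p95 <= result.threshold:
        return 0.0
    return profile.ir * (1.0 - result.threshold / p95)


def load_toxicity(path) -> dict[str, ToxicityReference]:
    """Toxicity table: columns contaminant_id, rfd_mg_per_kg_day, sf_per_mg_kg_day, source."""
    df = pd.read_csv(path)
    required = {"contaminant_id", "rfd_mg_per_kg_day", "sf_per_mg_kg_day", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"toxicity table {path} needs columns {sorted(required)}")
    table: dict[str, ToxicityReference] = {}
    for _, row in df.iterrows():
        rfd = row["rfd_mg_per_kg_day"]
        sf = row["sf_per_mg_kg_day"]
        table[str(row["contaminant_id"])] = ToxicityReference(
            contaminant_id=str(row["contaminant_id"]),
            rfd=None if pd.isna(rfd) else float(rfd),
            sf=None if pd.isna(sf) else float(sf),
            source=str(row["source"]),
        )
    return table


def default_toxicity() -> dict[str, ToxicityReference]:
    """Packaged default reference doses and slope factors (user-overridable)."""
    with resources.as_file(
        resources.files("dietrisk.data").joinpath("toxicity.csv")
    ) as p:
        return load_toxicity(p)
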