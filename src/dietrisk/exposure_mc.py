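"""Chemical intake from food consumption, deterministic and Monte Carlo.

The daily chemical intake (mg per kg body weight per day) from eating a
contaminated food is

    I = IR * C * EF * ED / (BW * AT) * 1e-3

with IR the food intake rate (g/day), C the tissue concentration (mg/kg),
EF the exposure frequency (days/year), ED the exposure duration (years),
BW the body weight (kg), AT the averaging time (days) and 1e-3 the g-to-kg
conversion.  The probabilistic simulation draws C from the fitted lognormal,
BW from a truncated normal, and optionally IR from a lognormal with median
at the survey intake rate; the sampled inputs are retained so that the
sensitivity stage can rank their influence.

Averaging-time convention: hazard quotients use AT = ED * 365 (intake
averaged over the exposure period), carcinogenic risks use a 70-year
lifetime AT = 70 * 365 = 25,550 days, the standard risk-assessment choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .dist_fit import LognormalFit

__all__ = [
    "DEMOGRAPHICS",
    "EF_DAYS_DEFAULT",
    "LIFETIME_YEARS_DEFAULT",
    "IR_GSD_DEFAULT",
    "BW_LOWER_BOUND_DEFAULT",
    "ExposureProfile",
    "IntakeDraws",
    "chemical_intake",
    "simulate_intake",
    "load_consumption",
    "load_demographics",
    "build_profiles",
    "default_consumption",
    "default_demographics",
]

DEMOGRAPHICS = ("girls", "boys", "women", "men")

EF_DAYS_DEFAULT = 365.0
LIFETIME_YEARS_DEFAULT = 70.0
#: Geometric SD of the intake-rate lognormal; 1.0 means the rate is fixed.
#: Survey intake rates are point values, but between-person variability in
#: consumption is substantial; a geometric SD of 1.5 is a typical dietary
#: survey spread and is documented prominently as an assumption.
IR_GSD_DEFAULT = 1.5
#: Body weights are sampled from a normal truncated below (resampling on
#: violation) to keep the denominator of the intake equation physical.
BW_LOWER_BOUND_DEFAULT = 20.0


@dataclass(frozen=True)
class ExposureProfile:
    """Demographic exposure factors for one (food, demographic) assessment."""

    demographic: str
    ir: float  # g/day, survey point value (lognormal median when ir_gsd > 1)
    ef: float  # days/year
    ed: float  # years
    bw_mean: float  # kg
    bw_sd: float  # kg
    at: float  # days
    ir_gsd: float = 1.0  # geometric SD; 1.0 = fixed intake rate
    bw_lower_bound: float = BW_LOWER_BOUND_DEFAULT

    def __post_init__(self) -> None:
        checks = [
            (self.ir >= 0, f"ir must be >= 0 (got {self.ir})"),
            (0 < self.ef <= 365, f"ef must be in (0, 365] (got {self.ef})"),
            (self.ed > 0, f"ed must be > 0 (got {self.ed})"),
            (self.bw_mean > 0, f"bw_mean must be > 0 (got {self.bw_mean})"),
            (self.bw_sd >= 0, f"bw_sd must be >= 0 (got {self.bw_sd})"),
            (self.at > 0, f"at must be > 0 (got {self.at})"),
            (self.ir_gsd >= 1, f"ir_gsd must be >= 1 (got {self.ir_gsd})"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid exposure profile {self.demographic!r}: {msg}")


@dataclass(frozen=True)
class IntakeDraws:
    """Simulated intakes with the sampled inputs retained for sensitivity."""

    intake: np.ndarray  # mg/kg/day
    sampled_c: np.ndarray  # mg/kg
    sampled_ir: np.ndarray  # g/day
    sampled_bw: np.ndarray  # kg
    seed: object

    def __post_init__(self) -> None:
        lengths = {
            len(self.intake),
            len(self.sampled_c),
            len(self.sampled_ir),
            len(self.sampled_bw),
        }
        if len(lengths) != 1:
            raise ValueError("intake and sampled-input sequences must share a length")

    def __len__(self) -> int:
        return len(self.intake)


def chemical_intake(
    c: float, ir: float, ef: float, ed: float, bw: float, at: float
) -> float:
    """Deterministic intake I = IR*C*EF*ED / (BW*AT) * 1e-3, in mg/kg/day."""
    for name, v in (("c", c), ("ir", ir), ("ef", ef), ("ed", ed), ("bw", bw), ("at", at)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite (got {v})")
    if bw <= 0:
        raise ValueError(f"body weight must be > 0 (got {bw})")
    if at <= 0:
        raise ValueError(f"averaging time must be > 0 (got {at})")
    return (ir * c * ef * ed) / (bw * at) * 1e-3


def _sample_body_weight(
    rng: np.random.Generator, n: int, mean: float, sd: float, lower: float
) -> np.ndarray:
    if sd == 0:
        if mean < lower:
            raise ValueError(f"fixed body weight {mean} kg below lower bound {lower} kg")
        return np.full(n, mean, dtype=float)
    bw = rng.normal(mean, sd, size=n)
    while True:
        bad = bw < lower
        if not bad.any():
            return bw
        bw[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def simulate_intake(
    fit: LognormalFit,
    profile: ExposureProfile,
    n_iter: int,
    seed: int | np.random.Generator,
) -> IntakeDraws:
    """Monte Carlo intake: draw C, IR and BW per iteration and apply Eq. above.

    C comes from the lognormal concentration fit, BW from a truncated normal,
    and IR from a lognormal with median ``profile.ir`` and geometric SD
    ``profile.ir_gsd`` (fixed when the GSD is 1).  Inputs are sampled
    independently.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1 (got {n_iter})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(n_iter)
    c = np.exp(rng.normal(fit.mu_log, fit.sigma_log, size=n))
    if profile.ir_gsd > 1:
        ir = profile.ir * np.exp(rng.normal(0.0, np.log(profile.ir_gsd), size=n))
    else:
        ir = np.full(n, profile.ir, dtype=float)
    bw = _sample_body_weight(
        rng, n, profile.bw_mean, profile.bw_sd, profile.bw_lower_bound
    )
    intake = (ir * c * profile.ef * profile.ed) / (bw * profile.at) * 1e-3
    return IntakeDraws(
        intake=intake, sampled_c=c, sampled_ir=ir, sampled_bw=bw, seed=seed
    )


def _packaged(name: str):
    return resources.files("dietrisk.data").joinpath(name)


def load_consumption(path) -> pd.DataFrame:
    """Consumption table: columns food_id, demographic, ir_g_per_day."""
    df = pd.read_csv(path)
    required = {"food_id", "demographic", "ir_g_per_day"}
    if not required.issubset(df.columns):
        raise ValueError(f"consumption table {path} needs columns {sorted(required)}")
    bad = set(df["demographic"]) - set(DEMOGRAPHICS)
    if bad:
        raise ValueError(f"unknown demographics in consumption table: {sorted(bad)}")
    return df


def load_demographics(path) -> pd.DataFrame:
    """Demographics table: columns demographic, bw_mean_kg, bw_sd_kg, ed_years."""
    df = pd.read_csv(path)
    required = {"demographic", "bw_mean_kg", "bw_sd_kg", "ed_years"}
    if not required.issubset(df.columns):
        raise ValueError(f"demographics table {path} needs columns {sorted(required)}")
    return df


def default_consumption() -> pd.DataFrame:
    """Packaged survey consumption rates (g/day) per food and demographic."""
    with resources.as_file(_packaged("consumption.csv")) as p:
        return load_consumption(p)


def default_demographics() -> pd.DataFrame:
    """Packaged body-weight and exposure-duration table per demographic."""
    with resources.as_file(_packaged("demographics.csv")) as p:
        return load_demographics(p)


def build_profiles(
    food_id: str,
    consumption: pd.DataFrame,
    demographics: pd.DataFrame,
    *,
    carcinogenic: bool,
    ef_days: float = EF_DAYS_DEFAULT,
    at_lifetime_years: float = LIFETIME_YEARS_DEFAULT,
    ir_gsd: float = IR_GSD_DEFAULT,
    bw_lower_bound: float = BW_LOWER_BOUND_DEFAULT,
) -> Mapping[str, ExposureProfile]:
    """One exposure profile per demographic with a consumption rate for the food.

    Carcinogenic assessments average intake over a lifetime
    (AT = at_lifetime_years * 365); non-carcinogenic ones over the exposure
    duration (AT = ED * 365).
    """
    rows = consumption[consumption["food_id"] == food_id]
    demo_idx = demographics.set_index("demographic")
    profiles: dict[str, ExposureProfile] = {}
    for _, row in rows.iterrows():
        demo = row["demographic"]
        if demo not in demo_idx.index:
            raise ValueError(f"no demographics entry for {demo!r}")
        d = demo_idx.loc[demo]
        ed = float(d["ed_years"])
        at = (at_lifetime_years if carcinogenic else ed) * 365.0
        profiles[demo] = ExposureProfile(
            demographic=str(demo),
            ir=float(row["ir_g_per_day"]),
            ef=ef_days,
            ed=ed,
            bw_mean=float(d["bw_mean_kg"]),
            bw_sd=float(d["bw_sd_kg"]),
            at=at,
            ir_gsd=ir_gsd,
            bw_lower_bound=bw_lower_bound,
        )
    return profiles
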