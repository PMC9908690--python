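"""Concentration records, censoring substitution, eligibility screening, summaries.

Tissue concentration data for wild-harvested foods are left-censored: any
measurement below the analytical method's minimum level of detection (MLOD)
is reported only as a non-detect.  Following common regulatory practice,
non-detects are substituted with half the detection limit before any
statistical analysis.  A (food, contaminant) dataset then enters the
probabilistic assessment only if it clears three screens: at least five
samples of the food, at least half the records detected, and a substituted
arithmetic mean above a class-specific concentration floor (0.01 mg/kg for
metals, 1.00e-4 mg/kg for organohalogens).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METAL",
    "ORGANOHALOGEN",
    "CLASS_MEAN_FLOORS",
    "MIN_SAMPLES",
    "MIN_DETECT_FRACTION",
    "PERCENTILE_SET",
    "ConcentrationRecord",
    "FoodContaminantDataset",
    "SummaryStats",
    "Eligibility",
    "substitute_nondetects",
    "eligible_for_assessment",
    "summarize",
    "percentile",
    "read_concentrations",
    "write_concentrations",
    "summary_table",
]

METAL = "metal"
ORGANOHALOGEN = "organohalogen"

#: Minimum substituted mean concentration (mg/kg) for a dataset to be assessed.
CLASS_MEAN_FLOORS: Mapping[str, float] = {METAL: 0.01, ORGANOHALOGEN: 1.00e-4}

#: Minimum number of samples of a food before any of its contaminants are assessed.
MIN_SAMPLES = 5

#: Minimum fraction of uncensored (valid detect) records.
MIN_DETECT_FRACTION = 0.50

#: Reporting percentiles used for concentration and risk summaries.
PERCENTILE_SET = (5, 10, 25, 50, 75, 90, 95, 99)

CONCENTRATION_COLUMNS = [
    "food_id",
    "contaminant_id",
    "contaminant_class",
    "value_mg_per_kg",
    "censored",
    "mlod_mg_per_kg",
]


@dataclass(frozen=True)
class ConcentrationRecord:
    """One tissue measurement, possibly censored at the detection limit.

    ``value`` is the measured concentration in mg/kg wet weight and is absent
    for censored records; ``mlod`` is the minimum level of detection in mg/kg
    and is mandatory for censored records.
    """

    food_id: str
    contaminant_id: str
    contaminant_class: str
    value: float | None = None
    censored: bool = False
    mlod: float | None = None

    def __post_init__(self) -> None:
        if self.contaminant_class not in CLASS_MEAN_FLOORS:
            raise ValueError(
                f"unknown contaminant class {self.contaminant_class!r} for "
                f"{self.food_id}/{self.contaminant_id}; expected one of "
                f"{sorted(CLASS_MEAN_FLOORS)}"
            )
        if self.censored:
            if self.mlod is None or not np.isfinite(self.mlod) or self.mlod <= 0:
                raise ValueError(
                    f"censored record for {self.food_id}/{self.contaminant_id} "
                    f"requires a strictly positive MLOD (got {self.mlod!r})"
                )
            if self.value is not None:
                raise ValueError(
                    f"censored record for {self.food_id}/{self.contaminant_id} "
                    "must not carry a measured value"
                )
        else:
            if self.value is None or not np.isfinite(self.value) or self.value < 0:
                raise ValueError(
                    f"detected record for {self.food_id}/{self.contaminant_id} "
                    f"requires a non-negative value (got {self.value!r})"
                )


@dataclass(frozen=True)
class FoodContaminantDataset:
    """All concentration records for one (food, contaminant) pair."""

    food_id: str
    contaminant_id: str
    contaminant_class: str
    records: tuple[ConcentrationRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for rec in self.records:
            if (rec.food_id, rec.contaminant_id) != (self.food_id, self.contaminant_id):
                raise ValueError(
                    f"record for {rec.food_id}/{rec.contaminant_id} does not "
                    f"belong to dataset {self.food_id}/{self.contaminant_id}"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_detects(self) -> int:
        return sum(1 for r in self.records if not r.censored)

    @property
    def detect_fraction(self) -> float:
        return self.n_detects / self.n if self.n else float("nan")


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive summary: mean, sample SD, extremes, reporting percentiles."""

    mean: float
    sd: float
    min: float
    percentiles: Mapping[int, float]
    max: float
    n: int


@dataclass(frozen=True)
class Eligibility:
    """Screening verdict with one machine-readable reason per failed criterion."""

    eligible: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def substitute_nondetects(dataset: FoodContaminantDataset) -> np.ndarray:
    """Return one concentration per record, replacing non-detects by MLOD/2.

    Detected values pass through unchanged and the record order is preserved.
    """
    out = np.empty(dataset.n, dtype=float)
    for i, rec in enumerate(dataset.records):
        if rec.censored:
            if rec.mlod is None or rec.mlod <= 0:
                raise ValueError(
                    f"record {i} of {dataset.food_id}/{dataset.contaminant_id} "
                    "is censored but has no positive MLOD"
                )
            out[i] = 0.5 * rec.mlod
        else:
            out[i] = rec.value
    return out


def eligible_for_assessment(dataset: FoodContaminantDataset) -> Eligibility:
    """Apply the three screening criteria; all are evaluated and reported."""
    if dataset.contaminant_class not in CLASS_MEAN_FLOORS:
        raise ValueError(f"unknown contaminant class {dataset.contaminant_class!r}")
    reasons: list[str] = []
    if dataset.n < MIN_SAMPLES:
        reasons.append(f"n < {MIN_SAMPLES} (n = {dataset.n})")
    if dataset.n and dataset.detect_fraction < MIN_DETECT_FRACTION:
        reasons.append(
            f"detect fraction {dataset.detect_fraction:.3f} below "
            f"{MIN_DETECT_FRACTION:.2f} ({dataset.n_detects}/{dataset.n})"
        )
    floor = CLASS_MEAN_FLOORS[dataset.contaminant_class]
    mean = float(np.mean(substitute_nondetects(dataset))) if dataset.n else 0.0
    if mean < floor:
        reasons.append(
            f"mean below class floor ({mean:.3g} < {floor:.3g} mg/kg for "
            f"{dataset.contaminant_class}s)"
        )
    return Eligibility(eligible=not reasons, reasons=tuple(reasons))


def percentile(values: Sequence[float] | np.ndarray, q: float | Sequence[float]):
    """Percentile by linear interpolation between order statistics.

    The interpolation point for probability p is p*(n-1)+1 in 1-based rank,
    the default convention of most statistical environments.  Used uniformly
    for concentration summaries and risk percentiles.
    """
    return np.percentile(np.asarray(values, dtype=float), q, method="linear")


def summarize(values: Sequence[float] | np.ndarray) -> SummaryStats:
    """Arithmetic mean, sample SD (n-1), extremes and reporting percentiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("summaries require finite, non-negative concentrations")
    pcts = percentile(arr, PERCENTILE_SET)
    return SummaryStats(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        min=float(arr.min()),
        percentiles={p: float(v) for p, v in zip(PERCENTILE_SET, pcts)},
        max=float(arr.max()),
        n=int(arr.size),
    )


def read_concentrations(path) -> list[FoodContaminantDataset]:
    """Read the concentration CSV dialect and group records per (food, contaminant).

    Expected columns: ``food_id, contaminant_id, contaminant_class,
    value_mg_per_kg, censored, mlod_mg_per_kg`` with ``censored`` encoded 0/1
    and an empty value permitted only for censored rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in CONCENTRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"concentration file {path} lacks columns {missing}")
    if df.empty:
        raise ValueError(f"concentration file {path} contains no records")
    datasets = []
    for (food, cont), grp in df.groupby(["food_id", "contaminant_id"], sort=True):
        classes = grp["contaminant_class"].unique()
        if len(classes) > 1:
            raise ValueError(
                f"{food}/{cont} carries conflicting contaminant classes {list(classes)}"
            )
        records = []
        for _, row in grp.iterrows():
            censored = bool(int(row["censored"]))
            value = row["value_mg_per_kg"]
            mlod = row["mlod_mg_per_kg"]
            records.append(
                ConcentrationRecord(
                    food_id=str(food),
                    contaminant_id=str(cont),
                    contaminant_class=str(classes[0]),
                    value=None if censored else float(value),
                    censored=censored,
                    mlod=None if pd.isna(mlod) else float(mlod),
                )
            )
        datasets.append(
            FoodContaminantDataset(
                food_id=str(food),
                contaminant_id=str(cont),
                contaminant_class=str(classes[0]),
                records=tuple(records),
            )
        )
    return datasets


def write_concentrations(datasets: Iterable[FoodContaminantDataset], path) -> None:
    """Write datasets in the standard concentration CSV dialect."""
    rows = []
    for ds in datasets:
        for rec in ds.records:
            rows.append(
                {
                    "food_id": rec.food_id,
                    "contaminant_id": rec.contaminant_id,
                    "contaminant_class": rec.contaminant_class,
                    "value_mg_per_kg": "" if rec.value is None else rec.value,
                    "censored": int(rec.censored),
                    "mlod_mg_per_kg": "" if rec.mlod is None else rec.mlod,
                }
            )
    pd.DataFrame(rows, columns=CONCENTRATION_COLUMNS).to_csv(path, index=False)


def summary_table(datasets: Iterable[FoodContaminantDataset]) -> pd.DataFrame:
    """One summary row per (food, contaminant) on substituted concentrations."""
    rows = []
    for ds in sorted(datasets, key=lambda d: (d.food_id, d.contaminant_id)):
        stats = summarize(substitute_nondetects(ds))
        row = {
            "food_id": ds.food_id,
            "contaminant_id": ds.contaminant_id,
            "contaminant_class": ds.contaminant_class,
            "n": ds.n,
            "n_detects": ds.n_detects,
            "mean": stats.mean,
            "sd": stats.sd,
            "min": stats.min,
        }
        row.update({f"p{p}": stats.percentiles[p] for p in PERCENTILE_SET})
        row["max"] = stats.max
        rows.append(row)
    return pd.DataFrame(rows)
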