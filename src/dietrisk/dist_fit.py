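"""Lognormal model of tissue concentrations and seeded Monte Carlo sampling.

Concentration data for environmental contaminants are right-skewed and
strictly positive, and the Monte Carlo stage samples them from a lognormal
distribution fitted to the (substituted) sample.  The fit is the closed-form
maximum-likelihood estimate on natural logs: ``mu_log`` is the mean log
concentration and ``sigma_log`` the log SD with the n denominator.  Skewness/
kurtosis diagnostics in the style of a Cullen-Frey plot are provided as
advisory output; they never switch the sampling family.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LognormalFit",
    "DistributionDiagnostics",
    "fit_lognormal_mle",
    "sample_lognormal",
    "cullen_frey_diagnostics",
    "substream",
]


@dataclass(frozen=True)
class LognormalFit:
    """Maximum-likelihood lognormal parameters on the natural-log scale."""

    mu_log: float
    sigma_log: float
    n: int

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError(f"sigma_log must be >= 0 (got {self.sigma_log})")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu_log))


@dataclass(frozen=True)
class DistributionDiagnostics:
    """Sample skewness/kurtosis with bootstrap replicates for a Cullen-Frey view."""

    skewness: float
    kurtosis: float
    bootstrap_points: tuple[tuple[float, float], ...]


def substream(root_seed: int, *labels: str) -> np.random.Generator:
    """Derive an independent random stream for one labelled assessment.

    The root seed is combined with CRC-32 hashes of the labels into a
    ``SeedSequence``, so each (food, contaminant, demographic) assessment has
    its own stream and adding one assessment never perturbs another.
    """
    entropy = [int(root_seed) & 0xFFFFFFFF]
    entropy += [zlib.crc32(lbl.encode("utf-8")) for lbl in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def fit_lognormal_mle(values) -> LognormalFit:
    """Closed-form lognormal MLE: mean and (n-denominator) SD of natural logs."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot fit a lognormal to an empty sample")
    bad = np.flatnonzero(~(arr > 0) | ~np.isfinite(arr))
    if bad.size:
        raise ValueError(
            f"lognormal fit requires strictly positive values; offending "
            f"record indices {bad.tolist()}"
        )
    logs = np.log(arr)
    return LognormalFit(
        mu_log=float(logs.mean()),
        sigma_log=float(logs.std(ddof=0)),
        n=int(arr.size),
    )


def sample_lognormal(
    fit: LognormalFit, n_iter: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n_iter`` concentrations from the fitted lognormal, reproducibly."""
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1 (got {n_iter})")
    if fit.sigma_log < 0:
        raise ValueError("sigma_log must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.exp(rng.normal(fit.mu_log, fit.sigma_log, size=int(n_iter)))


def cullen_frey_diagnostics(
    values, n_boot: int = 0, seed: int | np.random.Generator = 0
) -> DistributionDiagnostics:
    """Sample skewness and (Pearson) kurtosis with bootstrap replicates.

    Kurtosis is reported on the Pearson scale (normal = 3), matching the
    convention of the usual skewness-kurtosis diagnostic plot.  Bootstrap
    points are recomputed on same-size resamples with replacement.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("diagnostics require at least 4 values")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("diagnostics require finite, positive concentrations")
    if n_boot < 0:
        raise ValueError("n_boot must be >= 0")
    if np.ptp(arr) == 0:
        raise ValueError("skewness/kurtosis are undefined for a constant sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def moments(x: np.ndarray) -> tuple[float, float]:
        return (
            float(stats.skew(x, bias=True)),
            float(stats.kurtosis(x, fisher=False, bias=True)),
        )

    skew, kurt = moments(arr)
    boots = []
    for _ in range(int(n_boot)):
        res = rng.choice(arr, size=arr.size, replace=True)
        if np.ptp(res) == 0:  # degenerate resample carries no shape information
            boots.append((float("nan"), float("nan")))
        else:
            boots.append(moments(res))
    return DistributionDiagnostics(
        skewness=skew, kurtosis=kurt, bootstrap_points=tuple(boots)
    )
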