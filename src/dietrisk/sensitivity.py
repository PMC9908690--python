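"""Spearman rank sensitivity analysis of the Monte Carlo inputs.

After a simulation, the influence of each sampled input (tissue
concentration C, intake rate IR, body weight BW) on the hazard or risk
output is ranked by Spearman's rank correlation, mid-ranks for ties, with
p-values from the t-distribution approximation on n-2 degrees of freedom
(a permutation option exists for small samples).  An input held constant in
the simulation carries no rank information and is reported as
not-applicable rather than as a zero correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exposure_mc import IntakeDraws

__all__ = ["ALPHA", "SensitivityRow", "SensitivityTable", "spearman_rho", "sensitivity_analysis"]

ALPHA = 0.05

_PARAMETERS = ("C", "IR", "BW")


@dataclass(frozen=True)
class SensitivityRow:
    parameter: str  # one of C, IR, BW
    rho: float  # nan when not applicable
    p_value: float  # nan when not applicable
    significant: bool
    applicable: bool = True


@dataclass(frozen=True)
class SensitivityTable:
    rows: tuple[SensitivityRow, ...]

    def __getitem__(self, parameter: str) -> SensitivityRow:
        for row in self.rows:
            if row.parameter == parameter:
                return row
        raise KeyError(parameter)


def spearman_rho(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman's rho on mid-ranks with a t-approximation (or permutation) p-value.

    ``method`` is ``"t"`` (default, exact enough for Monte Carlo sample
    sizes) or ``"permutation"`` for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("Spearman correlation requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant sequence")
    if method == "t":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "permutation":
        def statistic(xs):
            return stats.spearmanr(xs, y).statistic

        rho = float(stats.spearmanr(x, y).statistic)
        perm = stats.permutation_test(
            (x,),
            statistic,
            permutation_type="pairings",
            n_resamples=2000,
            random_state=np.random.default_rng(0),
        )
        return rho, float(perm.pvalue)
    raise ValueError(f"unknown p-value method {method!r}")


def sensitivity_analysis(draws: IntakeDraws, output) -> SensitivityTable:
    """Rank C, IR and BW influence on the HQ/R output via Spearman's rho.

    One row per sampled input; inputs with zero variance (for example a fixed
    intake rate) are reported as not-applicable.
    """
    out = np.asarray(output, dtype=float)
    if out.shape[0] != len(draws):
        raise ValueError(
            f"output length {out.shape[0]} does not match draws length {len(draws)}"
        )
    samples = {
        "C": draws.sampled_c,
        "IR": draws.sampled_ir,
        "BW": draws.sampled_bw,
    }
    rows = []
    for name in _PARAMETERS:
        x = np.asarray(samples[name], dtype=float)
        if np.ptp(x) == 0:
            rows.append(
                SensitivityRow(
                    parameter=name,
                    rho=float("nan"),
                    p_value=float("nan"),
                    significant=False,
                    applicable=False,
                )
            )
            continue
        rho, p = spearman_rho(x, out)
        rows.append(
            SensitivityRow(parameter=name, rho=rho, p_value=p, significant=p < ALPHA)
        )
    return SensitivityTable(rows=tuple(rows))
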