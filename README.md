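# dietrisk

Probabilistic hazard and carcinogenic-risk assessment of contaminant
exposure from wild-harvested traditional foods (game, waterfowl, fish).

Subsistence diets are a known route of exposure to metals (Hg, Pb, Cd, ...)
and organohalogens (PCBs, PBBs, PBDEs, organochlorine pesticides) that
bioaccumulate in wildlife tissue. `dietrisk` implements the full assessment
chain used in dietary-exposure epidemiology:

1. **Censored concentration data.** Tissue measurements below the method's
   minimum level of detection (MLOD) are substituted at MLOD/2. A
   (food, contaminant) dataset is assessed only if the food has n ≥ 5
   samples, at least 50% of records are valid detects, and the substituted
   mean is at least 0.01 mg/kg (metals) or 1.00 × 10⁻⁴ mg/kg
   (organohalogens).
2. **Lognormal concentration model.** Closed-form maximum-likelihood fit on
   natural logs, with skewness/kurtosis (Cullen–Frey style) diagnostics.
3. **Monte Carlo intake.** 10,000 iterations of the intake equation

       I (mg/kg/day) = IR · C · EF · ED / (BW · AT) · 10⁻³

   with concentration C lognormal, body weight BW truncated-normal, and
   intake rate IR optionally lognormal around the survey value.
4. **Risk metrics.** Hazard quotient HQ = I / RfD against the reference
   dose, carcinogenic risk R = I · SF against the oral slope factor;
   assessments are flagged when the 95th percentile exceeds 1.00 (HQ) or
   1.00 × 10⁻⁶ (R), and the intake-rate reduction needed to bring a flagged
   risk back to threshold is back-computed from the linearity of I in IR.
5. **Sensitivity analysis.** Spearman rank correlation (with p-values) of
   each sampled input (C, IR, BW) against the output for flagged
   assessments.
6. **Synthetic data.** When only printed summary statistics of a study
   survive (n, detect count, median, range), a calibrated lognormal
   generator reconstructs left-censored datasets with the same structure so
   the whole pipeline can be replayed.

## Worked example

Reconstruct a goose/PCB-153 dataset from printed summaries (n = 23, 16
detects, median 4.50 × 10⁻⁴ mg/kg, range 9.00 × 10⁻⁵–5.40 × 10⁻³ mg/kg) and
estimate the men's carcinogenic risk (intake 21.90 g/day, body weight
96.08 ± 18.56 kg, 40-year exposure over a 70-year averaging lifetime,
PCB slope factor 2.0 (mg/kg/day)⁻¹):

```python
import dietrisk as dr
from dietrisk.reconstruction import reconstructed_risk_p95
from dietrisk.synthetic_data import GeneratorSpec

spec = GeneratorSpec(
    food_id="goose", contaminant_id="PCB 153", contaminant_class="organohalogen",
    n=23, detect_fraction=16/23, target_median=4.50e-4,
    target_min=9.00e-5, target_max=5.40e-3, mlod=9.00e-5,
)
fit = dr.calibrate_lognormal(spec)
print(f"calibrated lognormal: mu_log = {fit.mu_log:.3f}, sigma_log = {fit.sigma_log:.3f}")

men = dr.build_profiles("goose", dr.default_consumption(), dr.default_demographics(),
                        carcinogenic=True)["men"]
rec = reconstructed_risk_p95(spec, men, metric="R", sf=2.0,
                             n_iter=10_000, n_replicates=100, seed=1)
print(f"men's goose PCB-153 R95 (replicate mean): {rec.p95_mean:.3e}")
```

prints

```
calibrated lognormal: mu_log = -7.706, sigma_log = 1.014
men's goose PCB-153 R95 (replicate mean): 9.506e-07
```

`mu_log` is the log of the printed median; `sigma_log` is set so the
expected extremes of a 23-draw sample match the printed range. The R95 just
below 10⁻⁶ means the 95th-percentile lifetime excess cancer risk for this
consumption pattern sits at the de-minimis regulatory threshold — a slight
risk, concentrated in the upper tail of the concentration distribution.

## Command line

```sh
dietrisk fixture --out data/ --seed 1           # emit the synthetic study CSV
dietrisk run --concentrations data/concentrations.csv \
    --consumption consumption.csv --demographics demographics.csv \
    --toxicity toxicity.csv --out results/      # full pipeline
dietrisk reduce --risk-csv results/risk.csv --consumption consumption.csv
```

`run` writes `summary_stats.csv`, `fits.csv`, `risk.csv`,
`sensitivity.csv`, `boxplot.csv` (box at P5/P50/P95, whiskers at min/max)
and a `manifest.yaml` that echoes the full configuration, input digests and
every eligibility verdict, so a run is reproducible from its manifest
alone. Exit status 0 is a clean run, 2 a run with exclusions or warnings,
1 a failure. Packaged default tables (survey consumption rates, demographic
body weights and exposure durations, toxicity reference values with
sources) ship with the package and are fully user-overridable.

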