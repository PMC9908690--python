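# Methods

## Model and assumptions

The package estimates the probability distribution of chemical intake from
eating a contaminated food, and converts it into a non-carcinogenic hazard
quotient or an incremental lifetime cancer risk.

Intake per iteration is

    I = IR · C · EF · ED / (BW · AT) · 10⁻³   [mg/kg body weight/day]

| symbol | meaning | units | distribution |
|---|---|---|---|
| C | tissue concentration | mg/kg | lognormal, fitted to the (substituted) sample |
| IR | food intake rate | g/day | lognormal, median at the survey value, geometric SD `ir_gsd` (fixed when 1.0) |
| EF | exposure frequency | days/year | fixed, 365 |
| ED | exposure duration | years | fixed per demographic (9 for girls/boys, 40 for women/men — the population's median ages) |
| BW | body weight | kg | normal truncated below at 20 kg, demographic mean ± SD |
| AT | averaging time | days | fixed: ED · 365 for hazard quotients, 70 · 365 = 25,550 for carcinogenic risk |

The three sampled inputs are drawn independently; no rank-correlation
structure is imposed. HQ = I / RfD and R = I · SF are homogeneous of degree
one in every multiplicative input, which the threshold back-calculation
exploits: if the 95th-percentile risk R95 exceeds the 1.00 × 10⁻⁶
lifetime-attributable-risk threshold, reducing the median intake rate by
IR · (1 − 10⁻⁶/R95) rescales every percentile so that R95 lands exactly on
the threshold.

Threshold comparisons are strict inequalities: an assessment is flagged
when P95 > 1.00 (HQ) or P95 > 1.00 × 10⁻⁶ (R). Flagged assessments get a
Spearman rank sensitivity analysis (mid-ranks for ties; p-values from the
t-approximation on n − 2 degrees of freedom, with a permutation option for
small samples); inputs held constant are reported as not-applicable rather
than as zero correlations.

### Averaging-time convention

Dietary surveys report intake rates as daily averages, so EF is 365 days a
year and does not appear as a separate source of variability. Carcinogenic
risk uses the standard 70-year lifetime averaging time; hazard quotients
average over the exposure duration itself (so EF·ED/AT = 1 and the
non-carcinogenic intake is simply IR·C/BW·10⁻³).

### Intake-rate variability

Survey consumption tables give one point value per (food, demographic).
Sensitivity rankings of this kind of assessment only attribute influence to
IR if it varied, so the default treats the point value as the median of a
lognormal with geometric SD 1.5 — a typical between-person spread for food
consumption frequencies. This is the single largest modelling assumption in
the package; it is configurable (`ir_gsd`, set 1.0 for a fixed rate) and
echoed in every run manifest.

## Censored data and eligibility

Records below the detection limit are substituted at MLOD/2 before any
statistics; the substituted values feed both the eligibility screen and the
lognormal fit. Eligibility requires n ≥ 5 samples of the food, a valid
detect fraction ≥ 50%, and a substituted mean of at least 0.01 mg/kg for
metals or 1.00 × 10⁻⁴ mg/kg for organohalogens. All three criteria are
evaluated (not short-circuited) so exclusion reports are complete.

Percentiles everywhere (concentration summaries and risk percentiles) use
linear interpolation between order statistics at rank p·(n−1)+1, the
common statistical-environment default. Summary SDs use the n−1
denominator; the lognormal fit uses the maximum-likelihood n denominator on
logs. Both conventions are deliberate and live side by side.

## Synthetic-data generator

The generator reconstructs a concentration dataset from printed summary
statistics (sample size n, detect count, median, range):

- `mu_log = ln(median)` — the sample median maps to the lognormal median
  exactly.
- `sigma_log = ln(max/min) / (2z)`, z the standard-normal quantile at
  (n − 0.5)/n — the expected extreme order statistics of an n-draw sample
  match the printed range.
- The lowest round-half-even((1 − detect_fraction)·n) draws are converted
  to non-detects, because detection limits truncate from below.
- The generator's MLOD defaults to the printed minimum detected
  concentration, the standard stand-in when per-analyte detection limits
  are not published; MLOD/2 substitution therefore places non-detects just
  below the smallest detects, as in the source laboratory data.

What the generator emulates: right skew, left censoring, the printed
central value and spread, and the detect fraction. What it does not
emulate: batch-to-batch MLOD variation, multimodality (some real datasets
mix distinct sub-populations, e.g. fish-eating versus dabbling waterfowl),
spatial or seasonal structure, and tissue-type differences. Tests passing
on synthetic data therefore validate the pipeline's arithmetic and
statistical conventions, not the field representativeness of any
particular dataset.

The packaged study fixture spans nine foods; entries with printed summary
statistics are calibrated to them, the remainder are documented
placeholders set an order of magnitude above the class eligibility floor,
plus two deliberately ineligible datasets (low detect fraction; mean below
the metal floor) that exercise the exclusion paths.

## Reconstruction estimator and problem sizes

A single synthetic dataset of realistic size (n = 23 or 7) is a noisy
stand-in for a study's actual sample: the refitted `sigma_log` varies
enough to move the 95th-percentile risk by tens of percent between
realizations. Reconstructed percentiles are therefore reported as the mean
over independent replicate datasets, each with its own seeded substream:
10,000 Monte Carlo iterations per replicate, 100 replicates in
`scripts/acceptance.py` and 20 in the test suite. The whole reproduction
runs in seconds.

Seeding: a root seed expands into per-assessment substreams via
`SeedSequence([seed, crc32(label), ...])` over the food, contaminant,
demographic, metric and replicate labels, so results are bit-reproducible
and adding an assessment never perturbs existing ones.

## Design choices in open territory

- The lognormal family is hard-wired as the concentration model;
  skewness/kurtosis diagnostics are advisory only.
- Fits use the full substituted sample, not detects only, matching the
  global substitution step.
- Body weight must vary (it carries a nonzero sensitivity rank in this
  class of assessment) but only mean ± SD are available, hence the
  truncated normal; the 20 kg floor only matters for child demographics
  with large SDs.
- A record whose value ties its MLOD counts as a detect; censoring is
  driven solely by the flag.

## Known limitations

- **Threshold-straddling flags.** The reconstructed men's goose/PCB-153
  R95 averages just below 1.0 × 10⁻⁶ (≈ 0.95–1.05 × 10⁻⁶ depending on
  seed). MLOD/2 substitution pulls the refitted median ~30% below the
  printed detect median, which is enough to move a risk that was published
  slightly above the threshold to slightly below it. Single-realization
  flags for this assessment are coin flips, and the back-computed intake
  reduction is correspondingly unstable near zero.
- **Published demographic orderings need not be reproducible.** Intake is
  strictly increasing in IR/BW at fixed ED, so a demographic with a higher
  intake-to-body-weight ratio always carries the higher reconstructed
  risk. Published duck-consumption risks that rank women above men cannot
  emerge from the intake equation with the published consumption table;
  the reconstruction reports what the equation gives.
- **Spread mismatches.** A published 95th-percentile-to-median risk ratio
  below ~1.8 implies a total log-SD under ~0.37, which is incompatible
  with any lognormal fitted to a published concentration range spanning a
  factor of 10 or more — and with any intake-rate geometric SD above ~1.25
  even at zero concentration variance. Reconstructed upper percentiles for
  such datasets are systematically wider than the published ones.
- **No mixture, bolus-dose, seasonal, cooking-loss or bioaccessibility
  modelling**; contaminants are assessed singly on raw-tissue
  concentrations.
- Default toxicity reference values are shipped with per-row source
  strings and are meant to be overridden when an assessment has its own
  vetted table.
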