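# cpexposure

Probabilistic dietary exposure and risk assessment for **short- and
medium-chain chlorinated paraffins (SCCPs, C10–C13; MCCPs, C14–C17)** in
edible vegetable oils.

Chlorinated paraffins are persistent, fat-soluble industrial chemicals that
accumulate in lipid-rich foods. For a population consuming several oil types
(peanut, corn, soybean, sunflower, rapeseed, sesame), the package estimates
the distribution of the daily dose, characterizes risk against toxicological
reference points, and attributes exposure variability to its inputs. It is
written for exposure scientists and food-safety risk assessors who have a
(possibly left-censored) contaminant concentration panel and a consumption
survey, or who want to explore assessment designs on realistic synthetic
data.

## The model

Per Monte Carlo iteration, the estimated daily intake of an analyte is

```
EDI = Σ_i  P_i · C_i / Bw        [ng/kg bw/d]
```

with `P_i` the consumption of oil type *i* (g/d), `C_i` the analyte
concentration in that oil (ng/g), and `Bw` the body weight (kg). Each input
variable is fitted to a sampleable distribution — by default a *cumulative
anchor* model (minimum, maximum and decile anchor points with a linearly
interpolated CDF) — and 10,000 iterations are drawn. Risk is summarized by
the margin of exposure

```
MOE = BMDL10 / EDI               (BMDL10 in mg/kg bw/d, converted ×10⁶)
```

against the EFSA reference points (BMDL10 = 2.3 mg/kg bw/d for SCCPs, 36
for MCCPs); an MOE below 1000 flags a potential health concern. Sensitivity
uses a contribution-to-variance metric: normalized squared Spearman rank
correlations between each stochastic input (or input group) and the
simulated EDI.

Supporting steps implemented around the simulation: half-LOD substitution
for below-LOD concentrations (LODs 32 ng/g SCCP, 16 ng/g MCCP by default),
per-oil percentile trimming of implausible intakes (<P1 or >P99), exclusion
of incomplete survey individuals, congener-group (homologue) profile
marginals, and a synthetic-data generator with lognormal intakes, a
Gaussian-copula SCCP–MCCP pairing and censoring.

## Worked example

Library use, with fixed (point-mass) inputs so the arithmetic is visible —
30 g/d of one oil at 100 ng/g for a 60 kg person gives 30·100/60 = 50
ng/kg bw/d, and MOE = 2.3×10⁶/50 = 4.6×10⁴:

```python
from cpexposure import ExposureModel, ExposureConfig
from cpexposure.distributions import point_mass

model = ExposureModel(
    consumption_models={"peanut": point_mass(30.0)},     # g/d
    concentration_models={"SCCP": {"peanut": point_mass(100.0)}},  # ng/g
    bodyweight_model=point_mass(60.0),                   # kg
)
print(model.fit(ExposureConfig(n_iterations=1000, seed=1)).summary())
```

```
EDI (ng/kg bw/d)
analyte         mean    median       P95
SCCP           50.00     50.00     50.00

Margin of exposure (concern if MOE < 1000)
analyte   statistic        EDI         MOE  concern
SCCP      mean           50.00     4.6e+04    False
```

The full pipeline from the command line, on the calibrated synthetic demo
dataset (5,000 individuals, 50 concentration samples per oil, 10,000
iterations):

```
$ cpexposure run --seed 1 --outdir demo
assessment complete; artifacts in demo
  MCCP   mean    EDI    80.93 ng/kg bw/d   MOE 4.45e+05   concern=False
  MCCP   median  EDI    43.46 ng/kg bw/d   MOE 8.28e+05   concern=False
  MCCP   p95     EDI   292.99 ng/kg bw/d   MOE 1.23e+05   concern=False
  SCCP   mean    EDI    51.24 ng/kg bw/d   MOE 4.49e+04   concern=False
  SCCP   median  EDI    29.37 ng/kg bw/d   MOE 7.83e+04   concern=False
  SCCP   p95     EDI   180.40 ng/kg bw/d   MOE 1.27e+04   concern=False
```

Read: mean SCCP exposure about 51 ng/kg bw/d, the highest consumers (P95)
around 180 ng/kg bw/d; every margin of exposure is far above the concern
threshold of 1000, so no flag is raised. The output directory additionally
holds `report.json` (complete provenance-stamped report), the risk and
sensitivity CSV tables, per-analyte EDI draw vectors, the prepared input
tables and the fitted distributions as JSON. `cpexposure init` writes a
config template, `cpexposure fixtures` materializes the demo CSVs, and
`cpexposure report demo/report.json` pretty-prints a finished report.

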