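# Methods

## Scope and model

The package estimates the population distribution of the daily dose of
short- and medium-chain chlorinated paraffins (SCCPs/MCCPs) from edible
vegetable oil consumption. Per Monte Carlo iteration the estimated daily
intake is `EDI = Σ_i P_i·C_i / Bw` (ng/kg bw/d), with per-oil consumption
`P_i` (g/d), per-oil analyte concentration `C_i` (ng/g) and body weight
`Bw` (kg). Units compose directly (ng/g × g/d ÷ kg); there are no hidden
conversion factors anywhere except the single ×10⁶ (mg→ng) inside the
margin-of-exposure ratio.

Assumptions of the default (`fitted_independent`) mode: all input variables
are mutually independent; consumption and concentration are stationary over
the survey period; zero intake of an oil contributes zero dose (per-capita
exposure, not consumers-only). The alternative `bootstrap_paired` mode
resamples whole survey individuals, preserving the empirical pairing
between a person's oil intakes and body weight, for users holding
record-level data; concentrations are still drawn independently.

## Data preparation

* **Censoring**: concentrations below the limit of detection (defaults: 32
  ng/g SCCP, 16 ng/g MCCP) are replaced by LOD/2. The record keeps its
  censored flag so censoring rates stay reportable; the substitution is
  idempotent. Half-LOD substitution is a simple imputation that biases the
  lower tail upward when censoring is heavy; with the default demo
  censoring rates (roughly a tenth to a third of samples depending on oil)
  the effect on the EDI mean is small but not zero.
* **Trimming**: intakes strictly below the 1st or strictly above the 99th
  percentile of their oil type are removed; bounds are computed on the
  untrimmed per-oil set. Strict inequalities mean values equal to a bound
  survive.
* **Exclusion**: an individual missing intake, body weight, sex or age is
  removed entirely (all rows).
* **Percentile convention**: linear interpolation between order statistics
  (`numpy.percentile` default, the classical "type 7" definition), used
  identically for summaries, trimming bounds and anchor fitting.

## Distribution fitting

The default input model is the *cumulative anchor* family: the quantile
function linearly interpolates between the observed minimum, the decile
quantiles and the observed maximum (a piecewise-uniform density). This is
the behaviour of the cumulative-fit construct familiar from spreadsheet
risk tools; anchor percentiles are configurable, the deciles being the
declared default since no particular anchor set is canonical. Bounds
default to the observed extremes of the (trimmed) sample — the fit never
extrapolates beyond supported intake. Constant samples degenerate to a
point mass; fewer than 10 observations is an error recommending the
empirical bootstrap family instead. Parametric alternatives: lognormal
(exact MLE on log values) and gamma (scipy MLE with location fixed at 0).
Fitted models serialize to JSON for audit.

Sampling is inverse-CDF on a per-variable uniform stream. Each variable's
generator derives from `SeedSequence([run_seed, sha256(variable_name)])`,
so streams are mutually independent and adding or removing a variable never
perturbs the others' draws. This gives the engine exact additivity across
oils and bit-reproducibility under a fixed seed — both are tested.

## Risk characterization

`MOE = BMDL10×10⁶ / EDI`, evaluated at the mean, median and P95 of the
simulated EDI. Reference points default to the EFSA BMDL10 values (2.3
mg/kg bw/d SCCP, 36 mg/kg bw/d MCCP; registry-overridable). Concern is
flagged strictly below 1000; MOEs are displayed at 3 significant figures.

## Sensitivity

The contribution-to-variance metric is the squared Spearman rank
correlation ρ² between each stochastic input and the EDI draws, scaled to
percent, normalized by Σρ² only when that sum exceeds 1 (dependent inputs);
group contributions (consumption vs concentration vs body weight) sum
members' ρ² before normalization. The widely used spreadsheet metric of the
same name is proprietary; this definition is declared in the output's
`method` field. Because ρ² of independent inputs need not sum to 1, the
unattributed remainder is reported as an explicit `residual` line rather
than being spread across inputs. Constant inputs contribute 0 with a
warning. Spearman p-values (in the congener module's association statistic)
use scipy's t-distribution large-sample approximation.

## Synthetic data generator

The generator emulates the structure of a national consumption survey
paired with a market concentration panel:

* **Survey**: per oil, intake is lognormal among consumers with an optional
  non-consumer fraction; body weight is lognormal (default median 60 kg,
  σ = 0.15 — a declared assumption, since no body-weight distribution is
  available to calibrate against); sex is Bernoulli (51.6% female) and age
  uniform 18–80, carried only so completeness rules are exercisable.
  The pooled calibration (`SurveyGeneratorParams.pooled`) matches a median
  intake of 23.91 g/d and P95 of 67.23 g/d via the lognormal quantile
  closed form (μ = ln median, σ = ln(P95/median)/z₀.₉₅). The six-oil demo
  assigns rapeseed/peanut/corn medians above 25 g/d, sesame a long-tailed
  low-volume profile (population mean ≈ 0.8 g/d across everyone, ≈ 2.7 g/d
  among its 30% consumers), and consumer fractions such that mean total
  intake lands near 27 g/d.
* **Concentrations**: per oil, SCCP/MCCP means of tens to hundreds of ng/g
  (demo values 54/47, 121/211, 119/187, 165/82, 125/170, 79/132 ng/g for
  sunflower, peanut, soybean, sesame, rapeseed, corn), lognormal with
  CV = 0.6 by moment matching (μ = ln mean − ln(1+cv²)/2,
  σ = √ln(1+cv²)); the CV is a declared default, as only concentration
  ranges rather than dispersions are available. The SCCP–MCCP pairing is a
  Gaussian copula with Pearson parameter r = 2·sin(π·ρ_s/6) targeting a
  Spearman ρ_s of 0.411; since the lognormal transform is monotone, the
  rank correlation is preserved exactly in expectation. Draws below the
  analyte LOD are censored (value removed, true value retained in a
  separate truth table for oracle tests).
* **Congener matrices**: outer product of chain-length and chlorination
  marginals times total abundance, with mean-one multiplicative lognormal
  noise and renormalization; expected marginals equal the inputs. Default
  profiles: SCCP chain C10 > C11 > C13 > C12 (34/25/21/19, renormalized
  from rounded percentages to sum to 1) with Cl6–Cl8 carrying 65%; MCCP
  chain 36/42/16/6 with Cl5+Cl6+Cl8 at 65%.

What the generator does **not** reproduce: the real survey's demographic
joint structure (region, age strata, consumer overlap between oils),
inter-oil concentration correlations, and any seasonal or brand effects.
Passing tests therefore demonstrate correctness of the machinery and
qualitative agreement (right-skewed exposure, margins far above 1000, 
consumption-dominated variance), not a numerical reconstruction of any
particular survey's exposure distribution.

## Numerical choices and problem sizes

10,000 Monte Carlo iterations (default); demo runs use 5,000 synthetic
individuals and 50 concentration samples per oil; calibration checks use
50,000 individuals and 5,000 paired concentration samples — sizes at which
the targeted quantities are estimated well inside their test tolerances.
Ties in the dominant-congener ranking break deterministically (lower
carbon, then lower chlorine). Non-positive body-weight draws are resampled
with a logged count (impossible for the built-in positive-support families,
but user-supplied anchor fits can include zero). Anchor values are clipped
into overridden bounds and forced non-decreasing before constructing a fit.

## Known limitations

Half-LOD substitution rather than censored maximum-likelihood; no exposure
routes other than vegetable oils; no inter-oil concentration dependence in
the default mode; BMDL10 values are fixed constants, not derived from
dose–response data; the sensitivity metric is rank-based and can
under-attribute strongly non-monotone relationships.
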