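# Methods

This note documents the modelling choices behind `pahrisk`: the exposure and
risk equations, the parametric machinery, what the synthetic data emulate,
and the numerical decisions that affect reproducibility.

## Exposure model

Intake is survey-based: each respondent reports shrimp per meal, meals per
week, and a preferred commercial size class. Categories reported as ranges
("10–15 shrimp") resolve to their midpoints. The size class maps to grams
per shrimp through count-per-pound midpoints (small 51–60/lb, medium
41–50/lb, large 31–40/lb, extra-large 26–30/lb; 1 lb = 453.592 g); any
laboratory- or market-specific table can be substituted via CSV without code
changes. Respondents reporting zero consumption are retained at 0 g/day —
they dilute the population mean exactly as in an empirical survey summary.

The summary statistics reported for intake are the arithmetic mean, the
population SD (ddof = 0, so a single respondent has SD 0), and the 95th
percentile under linear interpolation on order statistics. The same
percentile estimator is used everywhere in the package, because
95th-percentile quantities are part of the headline outputs.

## Distribution fitting

Candidate families follow standard exposure-assessment practice: body weight
over {normal, log-normal, Pearson V}, intake rate over {Weibull, log-normal,
Pearson VI}. Pearson V is implemented as inverse-gamma and Pearson VI as
scaled beta-prime, the standard identifications. Two-parameter forms (plus
scale for Pearson VI) are fitted; location-shifted three-parameter variants
are not offered.

Estimation is maximum likelihood. Normal, log-normal and uniform use their
closed forms (MLE variance, ddof = 0). The numerically optimised families
use scipy's MLE with the location fixed at 0 and deterministic
method-of-moments starting values:

- inverse-gamma: α₀ = m²/v + 2, scale₀ = m(α₀ − 1);
- Weibull: shape₀ = (cv)^(−1.086) (the classic moment approximation),
  scale₀ = m / Γ(1 + 1/shape₀);
- beta-prime: fixed start (α, β, scale) = (4, 5, m), which matches the
  sample mean at the starting point.

Fixed starts make fits bit-reproducible. Fitting formally requires only
n ≥ 2 (the closed forms are defined there, and an all-equal sample is
rejected as degenerate), but BIC ranking is only meaningful at survey-scale
n; the package is normally used with n in the hundreds or more.

Ranking is by BIC = k ln n − 2 ln L̂, ascending; ties break by higher
log-likelihood, then family name. A family that fails to fit (degenerate
input, non-convergence, support violation) is recorded with its error and
ranked last rather than silently dropped. Which family "wins" is recorded,
never hard-coded: the full ranking travels with the results object and the
JSON output.

Truncated sampling (body weight on (0, 250) kg by default, bounds exposed in
configuration) uses the inverse CDF on the restricted quantile range
[F(a), F(b)], so draws target the renormalised truncated density exactly;
boundary hits from floating-point round-trips are nudged strictly inside
with `nextafter`. An interval carrying essentially no untruncated mass
(< 10⁻¹²) is rejected.

## Chemistry

Concentrations are carried in ng/g wet weight throughout; ng/g and µg/kg are
numerically identical, and the single conversion to ppm (mg/kg) happens at
the risk-engine boundary. Nondetects are imputed at LOD/√2, the conventional
substitution for left-censored environmental data; substitution never
changes a detected value and always maps a nondetect strictly below its LOD.

For noncancer endpoints, alkylated homologs are added to their parent PAH
under the equal-toxicity assumption, and anthracene + phenanthrene (plus
their homologs) pool into a single reference-dose group sharing RfD = 0.3
mg/kg-day. Analytes whose parent group carries no RfD are excluded from
noncancer totals.

For cancer, per-sample BaP-equivalent totals are RPF-weighted sums. Three
nested analyte tiers are supported: the seven carcinogenic PAHs
(benzo[a]anthracene, chrysene, benzo[b]fluoranthene, benzo[k]fluoranthene,
benzo[a]pyrene, indeno[1,2,3-c,d]pyrene, dibenzo[a,h]anthracene), plus the
unsubstituted PAHs, plus the alkylated homologs. Analytes without an
accepted RPF are excluded in the strict 7-cPAH tier and assigned a
caller-supplied default (conventionally the maximally conservative RPF = 1,
i.e. BaP-equivalent potency) in the expanded tiers. BaP-equivalents are
linear in each concentration and monotone nondecreasing across tiers by
construction.

### The packaged analyte table is a calibrated synthetic stand-in

The laboratory-specific LOD and RPF table behind the reference assessment is
not publicly available. The packaged `data/analytes.csv` therefore ships:

- U.S. EPA provisional RPFs for the 7 cPAHs (BaA 0.1, chrysene 0.001,
  BbF 0.1, BkF 0.01, BaP 1, IcdP 0.1, DahA 1), with a uniform cPAH
  detection limit back-calculated (0.668·√2/ΣRPF ≈ 0.409 ng/g) so the fully
  censored 7-cPAH BaP-equivalent total recomputes to exactly 0.668 µg/kg,
  the reference assessment's working value;
- a 16-analyte unsubstituted panel and a 10-group alkylated panel with
  LODs in the 2–4 ng/g range chosen so the censored tier totals (33.2 and
  49.5 µg BaPeq/kg under RPF = 1) reproduce the reference tier structure —
  in particular, adding the alkylated homologs multiplies risk by ≈ 1.49.

These numbers are configuration calibrated to published aggregate outputs,
not claims about any real laboratory's panel; a real table with the same
columns replaces them wholesale.

## Risk engines

Noncancer: ADI = C·IR/(BW·CF), HQ = ADI/RfD, with CF = 1000 g/kg. Cancer:
Risk = C_BaPeq·IR_kg·365·ED/(BW·28,470)·OSF, with IR converted from g/day to
kg/day once at configuration construction, ED in years (continuous uniform
on [5, 10] by default — the source range is given without a discretisation),
a 78-year averaging lifespan, and OSF = 7.3 (mg/kg/day)⁻¹.

Monte Carlo runs draw every input independently (no correlation structure is
asserted for the underlying survey), each from its own deterministic child
RNG stream derived from the single run seed, so adding a draw site never
perturbs the others and every output is reproducible bit-for-bit given the
seed. The default is 10,000 iterations; the Monte Carlo standard error of
the mean at that size is what the convergence tests budget against (3 MC
standard errors).

The tiered cancer analysis evaluates all tiers on one common draw of
(IR, BW, ED) and scales by each tier's BaPeq total, so every percentile —
not just the mean — is exactly proportional to the tier totals. Summaries
accumulate mean and SD in extended precision so that fully degenerate
(point-mass) inputs collapse to the deterministic point computation exactly,
a property the oracle tests rely on.

Histograms are relative-frequency histograms (counts / n, heights summing
to 1) over 50 equal-width bins from 0 to the 99.9th percentile for risk
outputs; draws beyond the display range are counted in the outer bin. This
is cosmetic and configurable.

A `constant` point-mass pseudo-family supplements the six parametric
families so any Monte Carlo input can be degenerated for oracle checks; it
is not a fitting candidate.

## What the synthetic generators emulate — and what they do not

The survey generator draws sex (even split), body weight from sex-specific
normals (67.5 / 58.9 kg, SD 11 kg) truncated to (30, 250) kg, and the three
consumption categories from configurable PMFs. The source reports only the
sex-specific means; SD 11 kg is a calibration knob chosen so the overall
mean lands near 63 kg with realistic adult spread. The category PMFs
(meal frequency mode "2–3 times a week", portion mode 10–15 shrimp, size
mode medium–large) imply a mean intake of 44.8 g/day, within 1% of the
reported 45.2 g/day. The lower truncation bound (30 kg) goes beyond the
source's ≤ 0 kg guard to avoid physiologically absurd synthetic adults.

The chemistry generator draws per-analyte log-normal concentrations
(geometric means 0.3–1.2 ng/g, geometric SDs ~1.5) with per-analyte
detection probabilities, for the eight analytes the reference study actually
detected.

Not emulated: inter-respondent correlation between body weight and
consumption, seasonal/temporal variation in consumption (including
disaster-driven reductions — the risk model assumes steady state),
inter-analyte concentration correlation within a composite, and
measurement error in the survey responses. Passing tests therefore
demonstrate that the pipeline's statistics behave correctly under the
stated generating model, not that any real population's risks equal these
numbers.

## Degenerate inputs and tie-breaks

- All-equal samples are rejected by `fit_mle` (σ → 0 is not a usable MLE for
  any candidate family); the `constant` family exists for simulation.
- Positive-support families reject nonpositive samples with a validation
  error naming the family.
- BIC ties (e.g. a family fitted twice) preserve a stable, documented order.
- Zero-intake respondents are kept in empirical summaries but excluded from
  positive-support intake fitting.
- An empty sample, empty tier list, or empty survey table is an error, not a
  silent empty result.

## Problem sizes

Default analyses use the survey-scale n = 115 respondents, 24 composite
samples, and 10,000 Monte Carlo iterations. Calibration checks in the test
suite use n = 10,000 synthetic respondents for tight convergence bounds, and
the BIC-consistency check uses 100 replicates at n = 5,000, sizes at which
the selection probability comfortably exceeds 95%.

## Known limitations

- The LOD/√2 substitution is a convention, not an estimator; for heavily
  censored analytes a maximum-likelihood censored-data fit would be less
  biased. It is used here because it is the convention the reference
  assessment and regulatory practice apply.
- RPF additivity with default RPF = 1 for data-poor analytes is
  deliberately conservative; as the tier analysis shows, it makes calculated
  risk grow with the analyte list irrespective of measured contamination.
- The deterministic hazard-quotient table uses the across-sample mean
  concentration; between-sample variability enters only through the Monte
  Carlo path.
- No dose-response modelling beyond the linear slope-factor paradigm, no
  age-dependent adjustment factors, no cooking-loss adjustment (the modelled
  population predominantly boils shrimp, which leaves PAH content largely
  unchanged).
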