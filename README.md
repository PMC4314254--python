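# pahrisk

Probabilistic dietary health-risk assessment for polycyclic aromatic
hydrocarbon (PAH) exposure through shrimp consumption, built for the kind of
population-specific assessment needed after an oil spill: a surveyed
community of frequent shrimp consumers (here modelled on Vietnamese-American
shrimp consumers of the U.S. Gulf Coast), locally harvested shrimp analysed
for a large PAH panel with most analytes below the detection limit, and both
noncancer and cancer risk propagated through Monte Carlo simulation.

It is aimed at exposure scientists and risk assessors who want the standard
U.S. EPA reference-dose / slope-factor machinery as a reproducible,
scriptable pipeline rather than a spreadsheet add-in.

## The model

**Intake.** Each survey respondent's shrimp intake rate (g/day) is

    IR = (shrimp per meal) × (g per shrimp) × (meals per week) / 7,

with grams per shrimp from commercial count-per-pound size classes
(e.g. "medium" = 41–50/lb → 453.592 g ÷ 45.5 ≈ 9.97 g).

**Exposure-factor distributions.** Body weight is fitted over
{normal, log-normal, Pearson V} and intake rate over
{Weibull, log-normal, Pearson VI} by maximum likelihood; candidates are
ranked by BIC = k ln n − 2 ln L̂. Pearson V is the inverse-gamma family
(shape α, scale β) and Pearson VI the scaled beta-prime family (α, β, scale).
Body weight is sampled from the winning family truncated to (0, 250) kg via
inverse-CDF on the restricted quantile range.

**Chemistry.** Nondetects are imputed at LOD/√2. For noncancer endpoints,
alkylated homologs are pooled into their parent PAH (equal-toxicity
assumption; anthracene and phenanthrene share one pooled reference-dose
group). For cancer, concentrations are aggregated to benzo[a]pyrene (BaP)
equivalents with relative potency factors (RPFs); analytes without an
accepted RPF are excluded from the strict 7-cPAH tier and conservatively
assigned RPF = 1 in the expanded tiers.

**Noncancer risk.** Average daily intake ADI = C·IR/(BW·CF) with C in ppm
(mg PAH/kg shrimp) and CF = 1000 g/kg; the hazard quotient is HQ = ADI/RfD,
with HQ > 1 flagging potential concern.

**Cancer risk.** Lifetime excess risk follows the linear slope-factor model

    Risk = [C_BaPeq · IR_kg · 365 · ED] / [BW · 28,470] × OSF,

with exposure duration ED ~ Uniform(5, 10) years, a 78-year (28,470-day)
averaging time, and OSF = 7.3 (mg/kg/day)⁻¹ for BaP. Monte Carlo simulation
(default 10,000 iterations) draws IR, BW and ED independently; the tiered
analysis (7 cPAHs → + unsubstituted PAHs → + alkylated PAHs) reuses common
random numbers so tier distributions scale exactly with the tier BaPeq
totals.

Because neither the raw survey nor the chemistry tables are public, the
package includes synthetic generators calibrated to the published summary
statistics (mean body weight 63 kg — 67.5 male / 58.9 female; mean intake
≈ 45 g/day; modal meal of 10–15 shrimp several times per week; per-analyte
log-normal concentrations < 2 ng/g with partial nondetection), so the whole
pipeline runs and is testable out of the box. See `docs/methods.md` for what
the generators do and do not emulate.

## Worked example

```python
import pahrisk as pr

model = pr.DietaryPAHRiskModel.from_synthetic(seed=1, n_respondents=115)
results = model.fit()
print(results.summary(n_iter=10_000, seed=1))
```

prints (abridged):

```
Respondents: 115    composite samples: 24
Mean body weight: 61.4 kg
Mean intake rate: 39.8 g/day (p95 124.6 g/day)

Fitted exposure-factor distributions (BIC-ranked, best first)
body weight [kg]:
    normal     params=(61.35, 10.96)  logL=-438.51  BIC=886.51
    lognormal  params=(4.1, 0.1817)  logL=-438.61  BIC=886.70
    pearson5   params=(29.98, 1779)  logL=-439.84  BIC=889.18
...
Hazard quotients (deterministic; HQ > 1 flags concern)
    naphthalene                RfD=0.02   HQ(mean)=7.6e-05  HQ(p95)=0.00024
...
Lifetime excess cancer risk by analyte tier (Monte Carlo, 10000 iterations)
    cpah7                mean=3.1e-07  p95=9e-07  p99=1.4e-06
    plus_unsubstituted   mean=1.5e-05  p95=4.5e-05  p99=7e-05
    plus_alkylated       mean=2.3e-05  p95=6.7e-05  p99=0.0001
```

Reading the output: every hazard quotient is orders of magnitude below 1 —
no noncancer concern at these tissue levels even for 95th-percentile
consumers. The 7-cPAH cancer risk (~3×10⁻⁷) sits below the 10⁻⁶ screening
level; expanding the analyte list under the conservative RPF = 1 assumption
pushes mean risk to ~10⁻⁵, and adding alkylated homologs multiplies it by
~1.5 — illustrating how additive potency assumptions for data-poor analytes
drive calculated risk, not measured contamination.

The same pipeline runs from the shell:

```bash
pahrisk all --seed 1 --iterations 10000 --out run1
pahrisk cancer --seed 1 --tier cpah7
```

writing the intake table, ranked distribution fits (JSON), the noncancer HQ
table, the per-tier cancer-risk table, relative-frequency histograms, and a
run manifest (seed, iteration count, configuration echo).

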