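# genassoc-meta

Meta-analysis of genetic-association studies that report genotype counts —
the kind of evidence synthesis used to settle whether a candidate
polymorphism (here the II/ID/DD genotypes of an insertion/deletion variant)
raises the risk of a binary outcome such as coronary restenosis after
percutaneous intervention. It is written for epidemiologists and
biostatisticians who have a table of per-study genotype (or allele) counts
for cases and controls and want the full analysis: per-study odds ratios
under the five standard genetic contrasts, random-effects pooling with
heterogeneity quantification, subgroup / meta-regression / cumulative /
leave-one-out analyses, and small-study-bias diagnostics.

## The model

Each study *i* contributes a 2×2 exposure-by-outcome table under a genetic
contrast (allele: D vs I allele counts; dominant: DD+ID vs II; recessive:
DD vs ID+II; heterozygous: ID vs II; homozygous: DD vs II), giving a log
odds ratio *yᵢ* = ln(aᵢdᵢ/bᵢcᵢ) with Woolf variance
*vᵢ* = 1/aᵢ + 1/bᵢ + 1/cᵢ + 1/dᵢ (Haldane–Anscombe 0.5 correction for
zero cells). Pooling uses the random-effects model

&nbsp;&nbsp;&nbsp;&nbsp;*yᵢ* ~ N(θᵢ, vᵢ),&nbsp;&nbsp; θᵢ ~ N(μ, τ²),

with the DerSimonian–Laird moment estimator
τ̂² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)), wᵢ = 1/vᵢ, where
Q = Σwᵢ(yᵢ − ȳ)² is Cochran's heterogeneity statistic (significant at
P < 0.10 by convention) and I² = 100·max(0, (Q − df)/Q) expresses the share
of variability beyond chance. When Q ≤ df, τ̂² = 0 and the estimator
coincides exactly with the fixed-effect inverse-variance mean. Funnel-plot
asymmetry is tested by Egger regression (OLS of yᵢ/seᵢ on 1/seᵢ; t-test on
the intercept with k−2 df) and the Begg–Mazumdar rank correlation;
moderators are examined one at a time by weighted meta-regression with
method-of-moments (or REML) residual τ².

Because published meta-analyses rarely reprint per-study genotype counts,
the package includes a synthetic-cohort generator with known truth
(allele frequency, per-allele OR, between-study variance, optional
publication-bias selection) so the whole pipeline is testable end to end,
plus a bundled 33-dataset restenosis study-characteristics table for the
ingestion and summary layer.

## Worked example

```python
import genassoc_meta as gm

# 12 synthetic cohorts: true per-allele OR 1.3, between-study variance 0.05
records = gm.simulate_studies(
    gm.SimulationConfig(k_studies=12, or_true=1.3, tau2=0.05, seed=42))
result = gm.MetaAnalysis.from_records(records, gm.GeneticModel.ALLELE).fit()
print(result.summary())
```

```
Meta-analysis (random effects), allele contrast
========================================================
studies (k)                      12
pooled OR                    1.2918
95% CI                       1.1354 1.4697
Z                            3.8882
P(Z)                       0.000101
Cochran Q (df=11)            70.6444
P(Q)                         <10^-4
I2 (%)                         84.4
tau2                         0.0439
--------------------------------------------------------
study weights (normalized):
  sim001                           0.0835
  ...
```

The pooled per-allele OR of 1.29 (95% CI 1.14–1.47) recovers the simulated
truth of 1.3; Q = 70.6 on 11 df (P < 10⁻⁴) and I² = 84% flag the strong
between-study heterogeneity injected through τ² = 0.05, and τ̂² = 0.044 is
its estimate. `result.or_ci_p()` renders the conventional table cell
`1.29 (1.14-1.47); 0.000101` and `classify_heterogeneity(result)` labels
the heterogeneity band (`strong`, significant).

The same analysis runs from a shell:

```
genassoc-meta simulate --out studies.csv --k 12 --or-true 1.3 --tau2 0.05 --seed 42
genassoc-meta run --studies studies.csv --out report/
```

which writes `report/report.json` plus flat TSV views (pooled results per
genetic model and subgroup, forest, funnel, cumulative and leave-one-out
tables). `gm.load_bundled_cohort()` loads the packaged restenosis
study-characteristics table (33 datasets, 11,193 patients), and
`gm.summarize_cohort` reproduces its per-intervention case/control totals.

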