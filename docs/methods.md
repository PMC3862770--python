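# Methods

## Scope and data model

The package analyses collections of genetic-association study datasets in
which each dataset reports, for cases and controls separately, the counts
of the three genotypes (II, ID, DD) of a biallelic insertion/deletion
variant — or, when a publication reports only allele totals, the I and D
allele counts. A dataset also carries study-level metadata used downstream:
publication year, ethnicity group (Asian / Caucasian / Other), intervention
type (stent vs balloon), follow-up duration in months, mean age, percent
male, a quality label (High / Median / Poor, ingested as an opaque label)
and an ACE-inhibitor treatment stratum. Validation is strict: counts are
either fully present per arm or fully missing (missing is never coerced to
zero), declared totals must match genotype sums, and rows failing any
invariant are rejected together with row-level diagnostics.

Inclusion filtering mirrors restenosis meta-analysis practice: angiographic
follow-up must fall inside a window (default 3–12 months; durations given
in years are converted at 12 months/year before comparison), and records
with no usable counts are dropped with reason `no_counts`. Control
genotypes are tested for Hardy–Weinberg equilibrium with a 1-df chi-square
goodness-of-fit test (allele frequency estimated from the same counts);
deviation at α = 0.05 sets a warning flag on the record but does not
exclude it — exclusion is available behind `exclude_hwe_violations` for
sensitivity analyses, since practice differs across meta-analyses.

## Effect estimation

Five genetic contrasts collapse a genotype distribution into a 2×2 table:
allele (D vs I, two alleles per person), dominant (DD+ID vs II), recessive
(DD vs ID+II), heterozygous (ID vs II) and homozygous (DD vs II); the last
two discard the excluded genotype class. The allele contrast treats the 2N
alleles as independent observations — the standard per-allele odds ratio
approximation, which ignores within-person allele dependence; under
Hardy–Weinberg proportions the approximation is exact in expectation.

Effects are unadjusted log odds ratios ln(ad/bc) with Woolf variance
1/a + 1/b + 1/c + 1/d. Adjusted estimates are deliberately out of scope:
source studies adjust for inconsistent covariate sets, so only count-based
ORs are comparable across studies. Zero cells receive the Haldane–Anscombe
correction: 0.5 (configurable) added to all four cells of the affected
table only, a minimal perturbation relative to correcting every study. A
table with all four cells zero is non-informative and is excluded from
pooling with a diagnostic rather than imputed.

## Pooling and heterogeneity

Pooling is inverse-variance. The random-effects model uses the
DerSimonian–Laird moment estimator of the between-study variance,

    tau2 = max(0, (Q - (k - 1)) / (sum(w) - sum(w^2)/sum(w))),  w = 1/se^2,

with Q the fixed-effect-weighted Cochran statistic. Weights are then
1/(se² + τ²). Reported results are always random-effects: when Q ≤ k−1 the
truncated τ² is zero and the output coincides bit-for-bit with the
fixed-effect fit, so homogeneous strata lose nothing. 95% CIs use the
normal quantile 1.959964 on the log scale with no small-sample (Knapp–
Hartung) adjustment, matching the classical inverse-variance practice of
the genetic-association literature this pipeline serves; overall
significance is a two-sided Z-test.

Heterogeneity is declared significant at P(Q) < 0.10, and
I² = 100·max(0, (Q−df)/Q) is banded as none-or-little (< 25%), moderate
(25–50%, both boundaries inclusive) and strong (> 50%). Edge conventions:
at k = 1, Q is defined as exactly 0 with P(Q) = 1 and I² = 0, so
single-study strata remain reportable; I² at Q = 0 is 0.

## Companion analyses

*Subgroups.* Stratification axes are ethnicity, study size, intervention
and ACE-inhibitor stratum. Every study maps to exactly one subgroup per
axis (missing values map to `unknown`), so subgroup k's always sum to the
overall k. The large/small study cut is total N ≥ 500 by default and
user-settable, because published analyses rarely state their cut and any
given split should be reproducible. The ACE-inhibitor comparison reuses the
subgroup machinery on treated/untreated strata.

*Meta-regression.* One moderator at a time (published analyses report
per-covariate P-values, not a joint model), weighted by 1/(se² + τ²_resid)
with residual τ² by the method of moments — the regression generalization
of DerSimonian–Laird, using the trace correction
E[Q_E] = (k−p) + τ²(tr W − tr[(X'WX)⁻¹X'W²X]) — or by REML (1-d profile
likelihood, bounded scalar optimization, tolerance 1e-10). The moment
method is the deterministic default; REML is provided for cross-checks.
Encodings: ethnicity Asian = 1 / Caucasian = 0 ("Other" has no defined
code and is treated as missing), study size as total N, follow-up in
months, age in years, sex as % male. Studies with a missing moderator are
dropped and recorded on the fit; fewer than 3 usable studies is an error.
A constant moderator degenerates to the intercept-only model, whose
intercept equals the DL pooled log OR exactly. Slope P-values are
two-sided normal.

*Cumulative and leave-one-out.* Cumulative meta-analysis re-pools after
each publication-year information step (same-year studies enter together),
using random effects at every step; the final step therefore reproduces
the overall result, which is asserted as an invariant. Leave-one-out
re-pools k times with one study omitted each time.

*Bias diagnostics.* Egger's test regresses the standardized effect y/se on
precision 1/se by unweighted OLS (the original formulation; a
precision-weighted variant is exposed behind `weighted=True`) and t-tests
the intercept on k−2 df; k ≥ 3 and non-identical standard errors are
required. Begg–Mazumdar correlates effects centered at the fixed-effect
mean and standardized by sqrt(se² − se²_pooled) with the sampling
variances, using the ties-corrected Kendall tau-b and its normal
approximation without continuity correction; all-tied variances return
tau = 0, P = 1. Both tests are provided because the field labels funnels
after Begg while usually quoting Egger P-values; Egger is the headline
asymmetry test in the full-analysis report.

## Synthetic cohorts

The generator emulates the cohort landscape of restenosis candidate-gene
meta-analyses. Per study: a study-specific log OR θᵢ ~ N(ln OR_true, τ²);
control genotypes Multinomial(n, HWE(p_D)); case genotype probabilities
obtained by tilting the control probabilities multiplicatively by exp(θᵢ)
per D allele and renormalizing. The tilt is logistic-consistent: a
Hardy–Weinberg population remains in Hardy–Weinberg form among cases at a
shifted allele frequency, so the allele-contrast log OR is centered at θᵢ
and the per-allele OR is the exact estimand. Defaults — 20 studies,
400–600 subjects per arm, p_D = 0.5, OR_true = 1.3, τ² = 0, years
1993–2012, 3–12-month follow-up, ~55% Asian studies, mostly male ~60-year
patients — mirror the size and mix of the published restenosis literature;
the metadata are realism only and carry no statistical weight unless used
as moderators. An optional selection rule suppresses studies with
allele-contrast P above a threshold with a given probability, emulating
publication bias; suppressed studies are redrawn until k "published"
studies accumulate.

What the generator does not emulate: linkage disequilibrium or multi-locus
effects, genotyping error, individual-level confounding, differential
follow-up or control groups containing future cases. Passing recovery
tests therefore demonstrates the estimators' correctness and calibration
under the stated sampling model, not robustness to those real-data
pathologies.

`recovery_experiment` runs the simulate→analyse loop and aggregates bias,
RMSE, CI coverage, mean τ̂² and Egger behaviour; replicate seeds are
spawned deterministically from the config seed.

## Verification set-up and problem sizes

The test suite and `scripts/acceptance.py` verify the estimators against
independently coded textbook oracles (plain-loop DL and Q, statsmodels OLS
for Egger, exhaustive O(k²) concordance counting for Kendall's tau) on
1,000 random instances with k ≤ 8, agreement to 1e-8 relative tolerance or
better. Calibration uses 300 replicates of the default 20-study cohort
(CI coverage of OR_true = 1.3 required within 93–97%, the Monte-Carlo band
around the nominal 95%) and 100 replicates each for the τ̂² ordering check
(true τ² = 0.2 vs 0). These sizes make the whole verification run in
seconds while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

- DL τ² is noisy at small k and the normal-quantile CI ignores the
  uncertainty in τ̂²; with very few studies coverage runs below nominal.
- Egger's intercept has an intrinsic nonzero expectation with log-OR data
  (the Woolf SE is mechanically correlated with the estimate), so its
  rejection rate deviates from nominal; the tests check route-consistency
  against the OLS oracle, not nominal size.
- The allele contrast's 2N-allele independence assumption fails under
  Hardy–Weinberg violation in either arm; the HWE flag exists to surface
  exactly that.
- Mantel–Haenszel fixed-effect pooling, trim-and-fill adjustment, Bayesian
  pooling, permutation meta-regression P-values and multi-moderator models
  are out of scope.
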