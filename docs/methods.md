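# Methods

## Model

`snprisk` assembles a multi-SNP logistic risk model without fitting
anything: every ingredient is taken from published summary statistics.

For SNP i with heterozygous odds ratio OR_het and (optionally)
homozygous odds ratio OR_hom, the coefficient is

    beta_i = ln(OR_het,i).

This is exact under the logistic model's own definition of an odds
ratio: a unit change in x_i multiplies the disease odds by e^beta_i,
so coding the heterozygote as x = 1 reproduces OR_het identically. The
homozygote, when OR_hom is published, is a *dummy variable* with

    x_hom = ln(OR_hom) / ln(OR_het),

chosen so that beta_i * x_hom = ln(OR_hom) exactly — the homozygote's
odds ratio is reproduced without assuming additivity of allele effects.

The intercept is calibrated per stratum (any labels; sex in the shipped
lung-cancer model) so that the population-average linear predictor
equals the logit of the stratum's average lifetime risk P0:

    beta_0 = logit(P0) - sum_i c_i.

The contribution c_i is the population expectation of the marker's term.
With both ORs it weights the two log-ORs by their Hardy-Weinberg
genotype frequencies at risk-allele frequency f:

    c_i = ln(OR_het) * 2f(1-f) + ln(OR_hom) * f^2.

With only a heterozygous OR the default ("literature") rule is

    c_i = ln(OR_het) * f,

the convention of the summary-statistics literature this model class
comes from. That rule is not the expectation of beta*x under the
prediction-time carrier coding (which would be
ln(OR_het) * (2f(1-f) + f^2)); replicating the published arithmetic is
the primary contract here, so the literature rule is the default and the
self-consistent alternative is available as `mode="hwe"` in
`marker_contribution` / `build_model`. The gap between the two is
reported nowhere implicitly — the test suite quantifies it explicitly on
the logit scale.

## Assumptions

* Markers are independent (no linkage disequilibrium) and in
  Hardy-Weinberg equilibrium in the target population.
* Published ORs are conditional effects transferable to the target
  population, and the allele frequencies refer to the *risk* allele in
  that population.
* The intercept absorbs all unmodelled risk factors; adding or removing
  a marker therefore only requires recalibrating beta_0, never refitting.
* Calibration is exact on the logit scale. On the risk scale the
  HWE-population mean risk exceeds P0 slightly (Jensen's inequality:
  the inverse logit is convex at low risks); the exhaustive-enumeration
  test brackets the mean risk between the Jensen lower bound and a
  second-order envelope 0.5 * var(LP) * sup|invlogit''|.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `or_threshold` (marker filter) | odds ratio | 1.15 | conventional curation floor for weak markers; applied to OR_het only, since curation predates homozygous estimates |
| `hom_encoding` | x-value | 1.0 | homozygote at a marker without OR_hom is treated as a carrier — the minimal assumption; 2.0 would impose log-additivity |
| calibration `mode` | — | `"literature"` | replicate the published beta*f rule; `"hwe"` for internal consistency |
| `missing` genotype policy | — | `"zero"` | a missing call contributes nothing and is counted in `n_missing` (reports flag such subjects); `"hwe"` imputes the population expectation of x |
| interval `level` | probability | 0.95 | delta-method band on the absolute risk |

## Genotype handling

Genotype TSV calls are unordered two-letter diploid calls classified by
counting the risk allele (0/1/2). VCF input is matched by rsID and the
risk-allele count is derived from GT against REF/ALT; a risk allele
matching neither REF nor ALT is warned about and treated as missing
(strict mode raises). Strand flips are never auto-resolved — silent
strand guessing is a classic failure mode of risk-score pipelines — and
A/T, C/G sites trigger an explicit ambiguity warning. Coordinates, where
present, are 1-based (VCF convention).

## Uncertainty intervals

The published variance of each coefficient is recovered from its OR's
95% CI, var(beta) = (ln(CI_hi/CI_lo) / (2 z))^2, the linear predictor's
variance is sum x_i^2 var(beta_i) (independence across markers, fixed
intercept), and the band is the inverse logit of LP +/- z sd. This is a
first-order delta-method approximation and is labelled as such in the
JSON report; it ignores covariance between OR estimates and uncertainty
in P0.

## Synthetic cohorts

The simulator emulates exactly the structure the model assumes: per SNP,
genotypes are drawn i.i.d. with probabilities ((1-f)^2, 2f(1-f), f^2);
case/control status is Bernoulli with probability from the calibrated
single-SNP model. It does **not** emulate linkage disequilibrium,
population stratification, genotyping error, strand mix-ups or
ascertainment bias — passing tests therefore demonstrate internal
consistency of the algorithm, not robustness of real-data risk scores to
those artefacts. Case/control recovery is exercised one SNP at a time
because marginal ORs from a multi-SNP logistic model are non-collapsible
and would not equal the generating conditional ORs.

Default problem sizes: 10 000 subjects for genotype-frequency recovery
(three-standard-error bands) and 200 000 subjects per marker for
odds-ratio recovery, large enough that every 2x2 cell's expectation is
well above 5 for the shipped markers. Seeds are mandatory in
`SimulationConfig` and recorded in all outputs; there is no wall-clock
seeding anywhere.

## Numerical choices

* All arithmetic is IEEE double precision; rounding to 3 decimals
  (risks) and 1 decimal (relative risks) happens only at display time in
  the TSV report and CLI tables. The shipped eight-SNP model's printed
  values are reproduced at that precision from full-precision arithmetic.
* `inverse_logit` is branch-stabilised for large |LP|.
* Cohort ranking sorts by descending absolute risk, stable for ties;
  tied risks share the smaller rank (competition ranking).
* An empty catalog is legal and calibrates to beta_0 = logit(P0).
* `x_hom` is undefined for a marker with OR_het = 1 and an OR_hom
  (division by ln 1 = 0); such a marker is rejected at model build.

## Known limitations

* The literature calibration rule for no-OR_hom markers (beta * f) mixes
  an allele-frequency expectation with genotype-coded prediction; the
  discrepancy is small for rare alleles but grows with f. Use
  `mode="hwe"` when internal consistency matters more than replicating
  published tables.
* No LD pruning, no strand harmonisation, no imputation from reference
  panels, no multi-allelic risk alleles, no non-SNP covariates.
* The delta-method interval understates uncertainty when ORs come from
  overlapping study populations.
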