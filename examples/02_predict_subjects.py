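"""Predict absolute and relative lifetime risk for a few genotyped subjects.

Builds the model, constructs three genotype profiles in memory (a
non-carrier, a heterozygote everywhere, and a risk-homozygote everywhere),
encodes them and prints the ranked risk report. Absolute risk is the
inverse logit of beta_0 + sum(beta_i x_i); relative risk divides it by the
stratum's average lifetime risk.
"""

from snprisk import (
    GenotypeClass,
    GenotypeProfile,
    PopulationBaseline,
    build_model,
    encode,
    load_lung_cancer_catalog,
    predict_cohort,
)

catalog = load_lung_cancer_catalog()
model = build_model(
    catalog,
    [PopulationBaseline("men", 0.0562), PopulationBaseline("women", 0.0256)],
)

profiles = [
    GenotypeProfile("non_carrier", "men",
                    {s: GenotypeClass.NON_CARRIER for s in catalog.snp_ids}),
    GenotypeProfile("heterozygote", "men",
                    {s: GenotypeClass.HETEROZYGOUS for s in catalog.snp_ids}),
    GenotypeProfile("homozygote", "women",
                    {s: GenotypeClass.HOMOZYGOUS_RISK for s in catalog.snp_ids}),
]
reports = predict_cohort([encode(p, model) for p in profiles], model)

print(f"{'rank':>4} {'subject':<14}{'abs risk':>9}{'rel risk':>9}  stratum")
for r in reports:
    print(f"{r.rank:>4} {r.subject_id:<14}{r.absolute_risk:>9.3f}{r.relative_risk:>9.1f}  {r.stratum}")

# A male carrying no risk allele sits below the male average (relative risk
# < 1); homozygous carriage of every risk allele multiplies the baseline
# severalfold but, being a logistic probability, can never reach 100%.
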