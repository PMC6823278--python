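"""Attach an approximate confidence band to one subject's predicted risk.

The published ORs carry sampling uncertainty; given each OR's 95% CI the
delta method propagates it: var(beta_i) is recovered from the CI width on
the log scale, var(LP) = sum x_i^2 var(beta_i), and the band is the
inverse logit of LP +/- 1.96 sd. The band is approximate (OR estimates
are treated as independent and the baseline as exact).
"""

from snprisk import (
    GenotypeClass,
    GenotypeProfile,
    PopulationBaseline,
    build_model,
    encode,
    load_lung_cancer_catalog,
    predict,
    risk_interval,
)

catalog = load_lung_cancer_catalog()
model = build_model(catalog, [PopulationBaseline("men", 0.0562)])

# heterozygous at the two strongest markers, non-carrier elsewhere
calls = {s: GenotypeClass.NON_CARRIER for s in catalog.snp_ids}
calls["rs1820453"] = GenotypeClass.HETEROZYGOUS
calls["rs716274"] = GenotypeClass.HETEROZYGOUS
subject = encode(GenotypeProfile("demo", "men", calls), model)

# illustrative 95% CIs for the two carried markers
or_cis = {"rs1820453": (1.18, 1.88), "rs716274": (1.39, 2.41)}

report = predict(subject, model)
lo, hi = risk_interval(subject, model, or_cis)
print(f"subject {report.subject_id}: absolute risk {report.absolute_risk:.3f}")
print(f"approximate 95% band: ({lo:.3f}, {hi:.3f})")
print(f"relative risk {report.relative_risk:.1f} vs the male baseline")
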