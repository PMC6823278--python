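"""Build the calibrated lung-cancer risk model from the packaged marker table.

Prints each SNP's log-odds coefficient (beta = ln OR_het), its
population-expected calibration contribution, their sum, and the
per-stratum intercepts that make the population-average linear predictor
reproduce the logit of the average lifetime risk.
"""

from snprisk import PopulationBaseline, build_model, load_lung_cancer_catalog

catalog = load_lung_cancer_catalog()
model = build_model(
    catalog,
    [PopulationBaseline("men", 0.0562), PopulationBaseline("women", 0.0256)],
)

print(f"{'snp_id':<12}{'beta':>8}{'x_hom':>8}{'contribution':>14}")
for c in model.coefficients:
    print(f"{c.snp_id:<12}{c.beta:>8.3f}{c.x_hom:>8.3f}{c.contribution:>14.3f}")
print(f"{'Sum':<28}{model.contribution_sum:>14.3f}")
for stratum, b0 in model.intercepts.items():
    print(f"intercept[{stratum}] = {b0:.3f}   (baseline p0 = {model.baselines[stratum]})")

# The intercept absorbs everything the selected SNPs do not explain: adding
# or dropping a marker and rebuilding re-derives it automatically.
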