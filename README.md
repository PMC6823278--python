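# snprisk

Logistic disease-risk prediction built directly from published per-SNP
odds ratios — no cohort refit required.

## The problem

Genome-wide association studies report each disease-associated SNP as an
odds ratio (OR) and a population allele frequency, one or a few markers
per publication. Turning that scattered literature into a single
calibrated risk predictor usually means either re-genotyping a large
cohort and refitting a logistic regression, or using ad hoc
likelihood-ratio multiplications that are not normalised (predicted
"risks" can exceed 100%). `snprisk` implements the direct alternative: a
multi-SNP logistic model whose coefficients come straight from the
literature and whose intercept is calibrated against the population's
average lifetime disease risk.

It is aimed at biostatisticians and bioinformaticians evaluating
polygenic risk models, and ships with a Hardy–Weinberg cohort simulator
so the whole pipeline can be exercised and validated without any real
genotype data.

## The model

Risk for a subject with genotype encoding x = (x₁, …, xₙ) is

    P = 1 / (1 + exp(−(β₀ + Σᵢ βᵢ xᵢ)))

with, for each SNP i:

* **coefficient** βᵢ = ln(OR_het,i), the log of the published
  heterozygous odds ratio;
* **encoding** xᵢ = 0 (non-carrier), 1 (heterozygote), or — when a
  homozygous OR is published — the dummy value
  x_hom = ln(OR_hom)/ln(OR_het), so that βᵢ·x_hom = ln(OR_hom) exactly.
  Without a homozygous OR the homozygote is coded as a carrier (x = 1;
  configurable);
* **intercept** β₀ = logit(P₀) − Σᵢ cᵢ per stratum (e.g. per sex), where
  P₀ is the stratum's average lifetime risk and cᵢ the marker's
  population-expected contribution: under Hardy–Weinberg equilibrium at
  risk-allele frequency f, cᵢ = ln(OR_het)·2f(1−f) + ln(OR_hom)·f² when
  both ORs exist, and cᵢ = ln(OR_het)·f when only the heterozygous OR is
  available (the source literature's convention; see
  `docs/methods.md`).

Because the intercept absorbs everything the selected SNPs do not
explain, markers can be added, dropped or updated and the model simply
recalibrates. Being a logistic probability, P is always strictly inside
(0, 1). Relative lifetime risk is P divided by the stratum's P₀.

## Worked example

The packaged marker table (`snprisk/data/lung_cancer_chinese.tsv`) holds
eight lung-cancer SNPs curated for Chinese individuals, with stratum
baselines of 5.62% (men) and 2.56% (women):

```python
from snprisk import PopulationBaseline, build_model, load_lung_cancer_catalog

catalog = load_lung_cancer_catalog()
model = build_model(catalog, [PopulationBaseline("men", 0.0562),
                              PopulationBaseline("women", 0.0256)])
```

Running `python examples/01_build_model.py` prints:

```
snp_id          beta   x_hom  contribution
rs1820453      0.399   1.256         0.174
rs716274       0.604   1.796         0.294
rs9981861      0.285   1.000         0.036
rs16951095     0.262   1.000         0.211
rs1051730      0.270   1.000         0.010
rs402710       0.166   1.000         0.121
rs2808630      0.199   1.000         0.044
rs7626795      0.148   1.000         0.031
Sum                                  0.921
intercept[men] = -3.742   (baseline p0 = 0.0562)
intercept[women] = -4.560   (baseline p0 = 0.0256)
```

Each `beta` is the log of that SNP's heterozygous OR; `x_hom` is the
homozygote encoding (1.256 for rs1820453 means a homozygote contributes
ln(1.65) to the linear predictor); `contribution` is the
population-expected term removed from logit(P₀) when calibrating, and
their sum (0.921) plus each intercept recovers logit(P₀) exactly. A man
carrying no risk allele has risk 1/(1+e^3.742) ≈ 0.023, i.e. a relative
risk of 0.4 versus the male average.

The other example scripts cover prediction and ranking
(`02_predict_subjects.py`), cohort simulation (`03_simulate_cohort.py`),
odds-ratio recovery from simulated case/control data
(`04_case_control_recovery.py`) and delta-method risk intervals
(`05_risk_interval.py`).

A command-line interface wraps the same pipeline:

```
snprisk build snprisk/data/lung_cancer_chinese.tsv --baselines baselines.json -o model.json
snprisk simulate <markers.tsv> --baselines baselines.json -n 100 --seed 7 -o cohort.tsv
snprisk predict model.json cohort.tsv -o report.tsv
```

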