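"""Synthetic cohorts with the statistical structure the model assumes.

Genotypes are drawn independently per SNP under Hardy-Weinberg
equilibrium (non-carrier / heterozygote / risk-homozygote with
probabilities (1-f)^2, 2f(1-f), f^2) — matching the model's own
assumptions: independent markers, no linkage disequilibrium. Case/control
status is drawn from the calibrated single-SNP logistic model itself, so
a contingency-table odds ratio computed from the simulated data should
recover the generating OR; this closes the loop on the beta = ln(OR)
correspondence.

Multi-SNP marginal ORs would NOT recover the per-SNP conditional ORs
(odds ratios are non-collapsible), which is why case/control recovery is
exercised one SNP at a time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import numpy as np

from .markers import MarkerCatalog, SNPMarker, hwe_genotype_freqs
from .model import PopulationBaseline, build_model, inverse_logit
from .genotypes import GenotypeClass, GenotypeProfile

__all__ = [
    "SimulationConfig",
    "CaseControlResult",
    "simulate_genotypes",
    "simulate_case_control",
]

_CLASS_BY_COUNT = (
    GenotypeClass.NON_CARRIER,
    GenotypeClass.HETEROZYGOUS,
    GenotypeClass.HOMOZYGOUS_RISK,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducible description of one simulation run.

    ``n_subjects`` maps stratum label -> cohort size. The seed is
    mandatory (no wall-clock seeding) and is recorded in all outputs.
    """

    catalog: MarkerCatalog
    baselines: tuple[PopulationBaseline, ...]
    n_subjects: Mapping[str, int]
    seed: int
    mode: Literal["cohort", "case_control"] = "cohort"

    def __post_init__(self) -> None:
        if not self.n_subjects:
            raise ValueError("n_subjects must name at least one stratum")
        for stratum, n in self.n_subjects.items():
            if n < 1:
                raise ValueError(f"n_subjects[{stratum!r}] must be >= 1, got {n}")
        known = {b.stratum for b in self.baselines}
        missing = set(self.n_subjects) - known
        if missing:
            raise ValueError(f"strata without a baseline: {sorted(missing)}")


def simulate_genotypes(config: SimulationConfig) -> list[GenotypeProfile]:
    """Draw genotype profiles under Hardy-Weinberg equilibrium.

    Subjects are named ``S0001, S0002, ...`` across strata in the order
    of ``config.n_subjects``. Two runs with the same config are
    identical.
    """
    rng = np.random.default_rng(config.seed)
    snp_ids = config.catalog.snp_ids
    probs = np.array(
        [
            [(1.0 - m.freq) ** 2, *hwe_genotype_freqs(m.freq)]
            for m in config.catalog
        ]
    )
    profiles: list[GenotypeProfile] = []
    counter = 0
    for stratum, n in config.n_subjects.items():
        # counts-of-risk-allele matrix, one column per SNP
        draws = np.stack(
            [rng.choice(3, size=n, p=probs[j]) for j in range(len(snp_ids))],
            axis=1,
        )
        for i in range(n):
            counter += 1
            calls = {
                snp_id: _CLASS_BY_COUNT[draws[i, j]]
                for j, snp_id in enumerate(snp_ids)
            }
            profiles.append(
                GenotypeProfile(
                    subject_id=f"S{counter:04d}", stratum=stratum, calls=calls
                )
            )
    return profiles


@dataclass(frozen=True)
class CaseControlResult:
    """2x2 genotype-by-status counts from a single-SNP simulation.

    Rows are heterozygous carriers vs. non-carriers (risk homozygotes are
    excluded: the generating OR is the heterozygote odds ratio). Columns
    are cases vs. controls.
    """

    snp_id: str
    seed: int
    n: int
    het_cases: int
    het_controls: int
    noncarrier_cases: int
    noncarrier_controls: int

    @property
    def sample_or(self) -> float:
        """Cross-product odds ratio of the 2x2 table."""
        return (self.het_cases * self.noncarrier_controls) / (
            self.het_controls * self.noncarrier_cases
        )

    def log_or_se(self) -> float:
        """Standard error of ln(sample OR) (Woolf's formula)."""
        return math.sqrt(
            1.0 / self.het_cases
            + 1.0 / self.het_controls
            + 1.0 / self.noncarrier_cases
            + 1.0 / self.noncarrier_controls
        )

    def or_ci(self, z: float = 1.96) -> tuple[float, float]:
        log_or = math.log(self.sample_or)
        half = z * self.log_or_se()
        return math.exp(log_or - half), math.exp(log_or + half)


def simulate_case_control(
    marker: SNPMarker,
    baseline: PopulationBaseline,
    n: int,
    seed: int,
) -> CaseControlResult:
    """Simulate one SNP end-to-end and tabulate carriers by disease status.

    Genotypes are drawn under HWE; disease status per subject is Bernoulli
    with probability from the calibrated single-SNP logistic model. The
    returned table counts heterozygotes vs. non-carriers against
    case/control status, so its cross-product OR estimates the marker's
    heterozygous OR. ``n`` should be large enough that every cell's
    expectation is at least 5; a zero cell triggers a warning suggesting
    a larger n or another seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    catalog = MarkerCatalog(markers=(marker,), population_label="simulated")
    model = build_model(catalog, [baseline])
    beta0 = model.intercept(baseline.stratum)
    entry = model.coefficients[0]

    het_f, hom_f = hwe_genotype_freqs(marker.freq)
    genotype = rng.choice(3, size=n, p=[1.0 - het_f - hom_f, het_f, hom_f])
    x = np.where(genotype == 2, entry.x_hom, genotype.astype(float))
    p = 1.0 / (1.0 + np.exp(-(beta0 + entry.beta * x)))
    case = rng.random(n) < p

    het = genotype == 1
    non = genotype == 0
    result = CaseControlResult(
        snp_id=marker.snp_id,
        seed=seed,
        n=n,
        het_cases=int(np.sum(het & case)),
        het_controls=int(np.sum(het & ~case)),
        noncarrier_cases=int(np.sum(non & case)),
        noncarrier_controls=int(np.sum(non & ~case)),
    )
    cells = (
        result.het_cases,
        result.het_controls,
        result.noncarrier_cases,
        result.noncarrier_controls,
    )
    if any(c == 0 for c in cells):
        warnings.warn(
            f"{marker.snp_id}: zero cell in the 2x2 table at n={n}, seed={seed}; "
            "increase n or resample with a different seed"
        )
    return result
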