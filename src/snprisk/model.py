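"""Calibrated logistic risk model built from published odds ratios.

The model is

    logit(P) = beta_0 + sum_i beta_i * x_i,      P = 1 / (1 + exp(-logit))

with one term per SNP. Each coefficient is taken directly from the
literature, beta_i = ln(OR_het,i), rather than fitted to cohort data.
The intercept beta_0 is calibrated so that the population-average linear
predictor reproduces the logit of the stratum's average lifetime disease
risk P0:

    beta_0 = logit(P0) - sum_i c_i

where c_i is the marker's population-expected contribution. When a
homozygous OR is reported, the homozygote is coded as a dummy variable
x = ln(OR_hom)/ln(OR_het) (so beta*x = ln(OR_hom) exactly) and c_i
weights both log-ORs by their Hardy-Weinberg genotype frequencies:

    c_i = ln(OR_het) * 2f(1-f) + ln(OR_hom) * f^2.

When only the heterozygous OR is known the contribution is the product
of the coefficient and the risk-allele frequency, c_i = ln(OR_het) * f
(the convention of the source literature; see the methods note for the
alternative "hwe" calibration mode).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

from .markers import MarkerCatalog, SNPMarker, hwe_genotype_freqs

__all__ = [
    "PopulationBaseline",
    "CoefficientEntry",
    "LogisticRiskModel",
    "beta_from_or",
    "marker_contribution",
    "calibrate_intercept",
    "build_model",
]

CalibrationMode = Literal["literature", "hwe"]


def logit(p: float) -> float:
    """ln(p / (1-p)) for p in (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie in (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def inverse_logit(lp: float) -> float:
    """1 / (1 + exp(-lp)), numerically stable for large |lp|."""
    if lp >= 0:
        return 1.0 / (1.0 + math.exp(-lp))
    z = math.exp(lp)
    return z / (1.0 + z)


@dataclass(frozen=True)
class PopulationBaseline:
    """Average lifetime disease risk for one stratum of the population.

    ``stratum`` is an arbitrary label ("men", "women", ...); ``p0`` the
    average lifetime risk in (0, 1).
    """

    stratum: str
    p0: float

    def __post_init__(self) -> None:
        if not self.stratum:
            raise ValueError("stratum label must be non-empty")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")


@dataclass(frozen=True)
class CoefficientEntry:
    """Per-SNP model term: coefficient, homozygote encoding, contribution.

    ``beta`` is ln(OR_het); ``x_hom`` the x-value assigned to the
    homozygous risk genotype (ln(OR_hom)/ln(OR_het) when a homozygous OR
    exists, else the configured carrier value); ``contribution`` the
    population-expected term subtracted during intercept calibration.
    """

    snp_id: str
    beta: float
    x_hom: float
    contribution: float


def beta_from_or(or_value: float) -> float:
    """Log-odds coefficient from an odds ratio: beta = ln(OR)."""
    if or_value <= 0.0:
        raise ValueError(f"odds ratio must be > 0, got {or_value}")
    return math.log(or_value)


def _x_hom(marker: SNPMarker, hom_encoding: float) -> float:
    if marker.or_hom is not None:
        beta = beta_from_or(marker.or_het)
        if beta == 0.0:
            raise ValueError(
                f"{marker.snp_id}: homozygous dummy encoding undefined for OR_het = 1"
            )
        return beta_from_or(marker.or_hom) / beta
    return hom_encoding


def marker_contribution(
    marker: SNPMarker,
    mode: CalibrationMode = "literature",
    hom_encoding: float = 1.0,
) -> float:
    """Population-expected calibration term of one marker.

    With a homozygous OR (both modes): ``ln(OR_het)*2f(1-f) + ln(OR_hom)*f^2``.
    Without one, mode ``"literature"`` uses ``ln(OR_het) * f`` while mode
    ``"hwe"`` uses the Hardy-Weinberg expectation of beta*x under the
    prediction-time encoding, ``ln(OR_het) * (2f(1-f) + hom_encoding*f^2)``.
    """
    beta = beta_from_or(marker.or_het)
    het_freq, hom_freq = hwe_genotype_freqs(marker.freq)
    if marker.or_hom is not None:
        return beta * het_freq + beta_from_or(marker.or_hom) * hom_freq
    if mode == "literature":
        return beta * marker.freq
    if mode == "hwe":
        return beta * (het_freq + hom_encoding * hom_freq)
    raise ValueError(f"unknown calibration mode {mode!r}")


def calibrate_intercept(
    catalog: MarkerCatalog,
    baseline: PopulationBaseline,
    mode: CalibrationMode = "literature",
    hom_encoding: float = 1.0,
) -> float:
    """Intercept beta_0 = logit(p0) - sum of marker contributions."""
    total = sum(marker_contribution(m, mode=mode, hom_encoding=hom_encoding) for m in catalog)
    return logit(baseline.p0) - total


@dataclass(frozen=True)
class LogisticRiskModel:
    """A calibrated multi-SNP logistic risk model.

    Immutable once built; rebuild from an updated catalog to add, drop or
    modify markers (the intercepts are re-derived automatically).
    """

    coefficients: tuple[CoefficientEntry, ...]
    intercepts: dict[str, float]
    baselines: dict[str, float]
    catalog: MarkerCatalog
    contribution_sum: float
    calibration_mode: CalibrationMode = "literature"
    hom_encoding: float = 1.0

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(c.snp_id for c in self.coefficients)

    @property
    def strata(self) -> tuple[str, ...]:
        return tuple(self.intercepts)

    def intercept(self, stratum: str) -> float:
        try:
            return self.intercepts[stratum]
        except KeyError:
            raise KeyError(
                f"no intercept for stratum {stratum!r}; known: {sorted(self.intercepts)}"
            ) from None

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        """Serialize to a flat, diffable JSON document (optionally to ``path``)."""
        doc = {
            "format": "snprisk-model",
            "version": 1,
            "population_label": self.catalog.population_label,
            "calibration_mode": self.calibration_mode,
            "hom_encoding": self.hom_encoding,
            "marker_table_sha256": self.catalog.provenance_hash(),
            "contribution_sum": self.contribution_sum,
            "baselines": self.baselines,
            "intercepts": self.intercepts,
            "coefficients": [
                {
                    "snp_id": c.snp_id,
                    "risk_allele": self.catalog[c.snp_id].risk_allele,
                    "beta": c.beta,
                    "x_hom": c.x_hom,
                    "contribution": c.contribution,
                }
                for c in self.coefficients
            ],
            "markers": [
                {
                    "snp_id": m.snp_id,
                    "risk_allele": m.risk_allele,
                    "freq": m.freq,
                    "or_het": m.or_het,
                    "or_hom": m.or_hom,
                    "source": m.source,
                }
                for m in self.catalog
            ],
        }
        text = json.dumps(doc, indent=indent)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LogisticRiskModel":
        """Load a model serialized by :meth:`to_json`.

        ``source`` is a path or a JSON string.
        """
        text = source
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        doc = json.loads(text)
        if doc.get("format") != "snprisk-model":
            raise ValueError("not a snprisk model document")
        catalog = MarkerCatalog(
            markers=tuple(
                SNPMarker(
                    snp_id=m["snp_id"],
                    risk_allele=m["risk_allele"],
                    freq=m["freq"],
                    or_het=m["or_het"],
                    or_hom=m.get("or_hom"),
                    source=m.get("source", ""),
                )
                for m in doc["markers"]
            ),
            population_label=doc.get("population_label", ""),
        )
        baselines = [PopulationBaseline(s, p) for s, p in doc["baselines"].items()]
        return build_model(
            catalog,
            baselines,
            mode=doc.get("calibration_mode", "literature"),
            hom_encoding=doc.get("hom_encoding", 1.0),
        )


def build_model(
    catalog: MarkerCatalog,
    baselines: Iterable[PopulationBaseline],
    mode: CalibrationMode = "literature",
    hom_encoding: float = 1.0,
) -> LogisticRiskModel:
    """Assemble a calibrated model from a catalog and stratum baselines.

    Coefficients follow catalog order. ``hom_encoding`` is the x-value
    given to homozygotes at markers without a homozygous OR (1.0 treats
    the homozygote as a carrier; 2.0 would be additive allele dosage).
    """
    baselines = list(baselines)
    if not baselines:
        raise ValueError("at least one population baseline is required")
    labels = [b.stratum for b in baselines]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate stratum labels: {labels}")

    coeffs = tuple(
        CoefficientEntry(
            snp_id=m.snp_id,
            beta=beta_from_or(m.or_het),
            x_hom=_x_hom(m, hom_encoding),
            contribution=marker_contribution(m, mode=mode, hom_encoding=hom_encoding),
        )
        for m in catalog
    )
    contribution_sum = sum(c.contribution for c in coeffs)
    intercepts = {b.stratum: logit(b.p0) - contribution_sum for b in baselines}
    return LogisticRiskModel(
        coefficients=coeffs,
        intercepts=intercepts,
        baselines={b.stratum: b.p0 for b in baselines},
        catalog=catalog,
        contribution_sum=contribution_sum,
        calibration_mode=mode,
        hom_encoding=hom_encoding,
    )
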