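"""Risk prediction: absolute risk, relative risk, intervals, cohort summaries.

Absolute lifetime risk is the inverse logit of the linear predictor
beta_0 + sum_i beta_i x_i; by construction it always lies strictly inside
(0, 1) — it cannot exceed 100% the way an unnormalised likelihood-ratio
product can. Relative lifetime risk divides the absolute risk by the
stratum's population-average lifetime risk P0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

from scipy.stats import norm

from .genotypes import EncodedProfile
from .model import LogisticRiskModel, inverse_logit

__all__ = [
    "RiskReport",
    "predict",
    "predict_cohort",
    "risk_interval",
    "cohort_summary",
    "CohortSummary",
    "write_report_tsv",
    "write_report_json",
]


@dataclass(frozen=True)
class RiskReport:
    """Predicted risk for one subject.

    ``rank`` is assigned within a reported cohort (1 = highest absolute
    risk; ties share the smaller rank) and is ``None`` for a standalone
    prediction. ``interval`` is an optional approximate 95% band on the
    absolute risk.
    """

    subject_id: str
    stratum: str
    absolute_risk: float
    relative_risk: float
    linear_predictor: float
    n_missing: int = 0
    rank: Optional[int] = None
    interval: Optional[tuple[float, float]] = None


def predict(encoded: EncodedProfile, model: LogisticRiskModel) -> RiskReport:
    """Absolute and relative risk for one encoded subject."""
    beta0 = model.intercept(encoded.stratum)
    if len(encoded.x) != len(model.coefficients):
        raise ValueError(
            f"x-vector length {len(encoded.x)} does not match the model's "
            f"{len(model.coefficients)} coefficients"
        )
    lp = beta0 + sum(c.beta * x for c, x in zip(model.coefficients, encoded.x))
    p = inverse_logit(lp)
    return RiskReport(
        subject_id=encoded.subject_id,
        stratum=encoded.stratum,
        absolute_risk=p,
        relative_risk=p / model.baselines[encoded.stratum],
        linear_predictor=lp,
        n_missing=encoded.n_missing,
    )


def predict_cohort(
    encoded_profiles: Sequence[EncodedProfile], model: LogisticRiskModel
) -> list[RiskReport]:
    """Predict every subject, then rank (see :func:`cohort_summary`)."""
    return cohort_summary([predict(e, model) for e in encoded_profiles], model).reports


def risk_interval(
    encoded: EncodedProfile,
    model: LogisticRiskModel,
    or_cis: Mapping[str, tuple[float, float]],
    level: float = 0.95,
) -> tuple[float, float]:
    """Approximate confidence bounds on a subject's absolute risk.

    Delta-method propagation of the published ORs' sampling uncertainty:
    each coefficient's variance is recovered from its OR's confidence
    interval, var(beta_i) = (ln(CI_hi/CI_lo) / (2 z))^2 with z the normal
    quantile for ``level``; the linear predictor's variance is
    sum x_i^2 var(beta_i); the band is the inverse logit of
    LP +/- z*sd(LP). The intercept is treated as fixed. Labelled
    approximate: it ignores OR estimation covariance and the baseline's
    own uncertainty.
    """
    z = norm.ppf(0.5 + level / 2.0)
    var_lp = 0.0
    for entry, x in zip(model.coefficients, encoded.x):
        if x == 0.0:
            continue
        if entry.snp_id not in or_cis:
            raise KeyError(f"no OR confidence interval supplied for {entry.snp_id}")
        lo, hi = or_cis[entry.snp_id]
        if not 0.0 < lo <= hi:
            raise ValueError(f"{entry.snp_id}: invalid CI bounds ({lo}, {hi})")
        var_beta = (math.log(hi / lo) / (2.0 * z)) ** 2
        var_lp += x * x * var_beta
    lp = model.intercept(encoded.stratum) + sum(
        c.beta * x for c, x in zip(model.coefficients, encoded.x)
    )
    half = z * math.sqrt(var_lp)
    return inverse_logit(lp - half), inverse_logit(lp + half)


@dataclass(frozen=True)
class CohortSummary:
    """Ranked cohort report plus per-stratum mean absolute risks."""

    reports: list[RiskReport]
    stratum_means: dict[str, float]
    stratum_counts: dict[str, int]


def cohort_summary(
    reports: Sequence[RiskReport], model: LogisticRiskModel
) -> CohortSummary:
    """Sort a cohort by descending absolute risk, rank it, and average it.

    The sort is stable for ties; tied risks share the smaller rank
    (competition ranking). Means are arithmetic, per stratum.
    """
    if not reports:
        raise ValueError("cohort_summary requires at least one report")
    ordered = sorted(
        range(len(reports)), key=lambda i: -reports[i].absolute_risk
    )
    ranked: list[RiskReport] = []
    prev_risk: Optional[float] = None
    prev_rank = 0
    for pos, idx in enumerate(ordered, start=1):
        r = reports[idx]
        rank = prev_rank if r.absolute_risk == prev_risk else pos
        ranked.append(replace(r, rank=rank))
        prev_risk, prev_rank = r.absolute_risk, rank

    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in reports:
        sums[r.stratum] = sums.get(r.stratum, 0.0) + r.absolute_risk
        counts[r.stratum] = counts.get(r.stratum, 0) + 1
    means = {s: sums[s] / counts[s] for s in sums}
    return CohortSummary(reports=ranked, stratum_means=means, stratum_counts=counts)


def write_report_tsv(reports: Sequence[RiskReport], path: str | Path) -> None:
    """Cohort report as TSV: subject_id, absolute_risk, relative_risk, stratum.

    Risks are displayed to 3 decimals and relative risks to 1, the
    conventional reporting precision; full precision lives in the JSON
    variant.
    """
    with Path(path).open("w") as fh:
        fh.write("subject_id\tabsolute_risk\trelative_risk\tstratum\n")
        for r in reports:
            fh.write(
                f"{r.subject_id}\t{r.absolute_risk:.3f}\t{r.relative_risk:.1f}\t{r.stratum}\n"
            )


def write_report_json(reports: Sequence[RiskReport], path: str | Path) -> None:
    """Full-precision cohort report (linear predictor, missing count, interval)."""
    doc = [
        {
            "subject_id": r.subject_id,
            "stratum": r.stratum,
            "absolute_risk": r.absolute_risk,
            "relative_risk": r.relative_risk,
            "linear_predictor": r.linear_predictor,
            "n_missing": r.n_missing,
            "rank": r.rank,
            "interval": None if r.interval is None else list(r.interval),
            "approximate_interval": r.interval is not None,
        }
        for r in reports
    ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
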