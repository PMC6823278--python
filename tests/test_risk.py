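import itertools
import math

import pytest

from snprisk import (
    EncodedProfile,
    RiskReport,
    cohort_summary,
    inverse_logit,
    logit,
    predict,
    risk_interval,
)
from conftest import COHORT_48


def enc(x, stratum="men", subject="s", n_missing=0):
    return EncodedProfile(subject, stratum, tuple(x), n_missing)


class TestPredict:
    def test_all_zero_profile_is_baseline_carrier_free_risk(self, model):
        r = predict(enc([0.0] * 8), model)
        assert r.absolute_risk == pytest.approx(1 / (1 + math.exp(3.742)), abs=5e-5)
        assert r.linear_predictor == pytest.approx(model.intercepts["men"], abs=1e-15)

    @pytest.mark.parametrize(
        "risk, stratum, expected_rr",
        [(0.283, "men", 5.0), (0.162, "women", 6.3)],
    )
    def test_relative_risk_is_ratio_to_stratum_baseline(self, model, risk, stratum, expected_rr):
        """Published convention: relative risk = absolute risk / stratum p0."""
        rr = risk / model.baselines[stratum]
        assert round(rr, 1) == expected_rr

    def test_risk_is_exact_inverse_logit_of_linear_predictor(self, model):
        for x in ([0.0] * 8, [1.0] * 8, [c.x_hom for c in model.coefficients]):
            r = predict(enc(x), model)
            assert 0 < r.absolute_risk < 1
            assert logit(r.absolute_risk) - r.linear_predictor == pytest.approx(0, abs=1e-12)
            assert r.relative_risk == pytest.approx(
                r.absolute_risk / model.baselines["men"], rel=1e-15
            )

    def test_exhaustive_genotype_enumeration_matches_direct_formula(self, model):
        """Brute-force oracle: all 3^8 genotype combinations, risk computed
        straight from the logistic formula, must match predict exactly; no
        combination can escape (0, 1)."""
        betas = [c.beta for c in model.coefficients]
        x_homs = [c.x_hom for c in model.coefficients]
        max_delta = 0.0
        for stratum in ("men", "women"):
            b0 = model.intercepts[stratum]
            for combo in itertools.product((0, 1, 2), repeat=8):
                x = [0.0 if g == 0 else 1.0 if g == 1 else x_homs[i] for i, g in enumerate(combo)]
                direct = 1.0 / (1.0 + math.exp(-(b0 + sum(b * xi for b, xi in zip(betas, x)))))
                got = predict(enc(x, stratum=stratum), model).absolute_risk
                max_delta = max(max_delta, abs(got - direct))
                assert 0.0 < got < 1.0
        assert max_delta < 1e-12

    def test_unknown_stratum_rejected(self, model):
        with pytest.raises(KeyError, match="child"):
            predict(enc([0.0] * 8, stratum="child"), model)

    def test_monotone_in_each_genotype(self, model):
        base = predict(enc([0.0] * 8), model).absolute_risk
        for i in range(8):
            x = [0.0] * 8
            x[i] = 1.0
            assert predict(enc(x), model).absolute_risk > base


class TestRiskInterval:
    def test_all_zero_x_collapses_to_point(self, model):
        lo, hi = risk_interval(enc([0.0] * 8), model, or_cis={})
        point = predict(enc([0.0] * 8), model).absolute_risk
        assert lo == pytest.approx(point, abs=1e-15)
        assert hi == pytest.approx(point, abs=1e-15)

    def test_single_snp_interval_matches_delta_formula(self, model):
        from scipy.stats import norm

        x = [1.0] + [0.0] * 7
        cis = {"rs1820453": (1.2, 1.8)}
        lo, hi = risk_interval(enc(x), model, or_cis=cis)
        z = norm.ppf(0.975)
        sd = math.log(1.8 / 1.2) / (2 * z)
        lp = model.intercepts["men"] + model.coefficients[0].beta
        assert lo == pytest.approx(inverse_logit(lp - z * sd), abs=1e-12)
        assert hi == pytest.approx(inverse_logit(lp + z * sd), abs=1e-12)
        assert lo < predict(enc(x), model).absolute_risk < hi

    def test_wider_ci_widens_the_interval(self, model):
        x = [1.0] + [0.0] * 7
        lo1, hi1 = risk_interval(enc(x), model, {"rs1820453": (1.2, 1.8)})
        lo2, hi2 = risk_interval(enc(x), model, {"rs1820453": (1.1, 2.0)})
        assert hi2 - lo2 > hi1 - lo1

    def test_missing_ci_names_the_snp(self, model):
        with pytest.raises(KeyError, match="rs716274"):
            risk_interval(enc([0.0, 1.0] + [0.0] * 6), model, {"rs1820453": (1.2, 1.8)})


class TestCohortSummary:
    @pytest.fixture()
    def published_reports(self, model):
        reports = []
        for sid, risk, sex in COHORT_48:
            stratum = "men" if sex == "M" else "women"
            p0 = model.baselines[stratum]
            reports.append(
                RiskReport(
                    subject_id=sid,
                    stratum=stratum,
                    absolute_risk=risk,
                    relative_risk=risk / p0,
                    linear_predictor=logit(risk),
                )
            )
        return reports

    def test_published_cohort_stratum_means(self, model, published_reports):
        """38 men average 8.9%, 10 women 5.5% (printed rounding)."""
        summary = cohort_summary(published_reports, model)
        assert summary.stratum_counts == {"men": 38, "women": 10}
        assert round(summary.stratum_means["men"], 3) == 0.089
        assert round(summary.stratum_means["women"], 3) == 0.055

    def test_ranking_descending_with_ties_sharing_smaller_rank(self, model, published_reports):
        summary = cohort_summary(published_reports, model)
        risks = [r.absolute_risk for r in summary.reports]
        assert risks == sorted(risks, reverse=True)
        assert summary.reports[0].subject_id == "17"
        assert summary.reports[0].rank == 1
        # subjects 23 and 27 tie at 0.174 and share rank 2
        tied = [r for r in summary.reports if r.absolute_risk == 0.174]
        assert {r.rank for r in tied} == {2}
        next_after = [r for r in summary.reports if r.absolute_risk == 0.152]
        assert next_after[0].rank == 4

    def test_single_report_mean_is_itself(self, model):
        r = RiskReport("a", "men", 0.1, 0.1 / 0.0562, logit(0.1))
        summary = cohort_summary([r], model)
        assert summary.stratum_means == {"men": 0.1}
        assert summary.reports[0].rank == 1

    def test_empty_cohort_rejected(self, model):
        with pytest.raises(ValueError):
            cohort_summary([], model)


class TestPopulationConsistency:
    def test_mean_linear_predictor_under_hwe_matches_calibration(self, catalog, baselines):
        """Weighted over all 3^8 genotype states with HWE probabilities, the
        mean linear predictor equals logit(p0) plus the documented gap from
        the literature beta*f rule for markers without a homozygous OR; the
        gap vanishes in 'hwe' calibration mode. Mean risk itself is
        bracketed by Jensen's inequality from below and a second-order
        envelope (0.5 * var(LP) * sup|invlogit''|) from above, both computed
        by the enumeration oracle — it need not equal p0 on the risk scale."""
        from snprisk import build_model, hwe_genotype_freqs, marker_contribution

        for mode in ("literature", "hwe"):
            model = build_model(catalog, baselines, mode=mode)
            b0 = model.intercepts["men"]
            p0 = model.baselines["men"]
            # per-SNP expected beta*x and var(beta*x) under HWE with the
            # prediction-time encoding (markers are independent)
            mean_lp = b0
            gap = 0.0
            var_lp = 0.0
            for entry, marker in zip(model.coefficients, model.catalog):
                het, hom = hwe_genotype_freqs(marker.freq)
                e_x = het + hom * entry.x_hom
                e_x2 = het + hom * entry.x_hom**2
                mean_lp += entry.beta * e_x
                var_lp += entry.beta**2 * (e_x2 - e_x**2)
                gap += entry.beta * e_x - marker_contribution(marker, mode=mode)
            if mode == "hwe":
                assert gap == pytest.approx(0.0, abs=1e-12)
            assert mean_lp == pytest.approx(logit(p0) + gap, abs=1e-12)

            # exhaustive mean risk, HWE-weighted
            import itertools

            probs = []
            xs = []
            for marker, entry in zip(model.catalog, model.coefficients):
                het, hom = hwe_genotype_freqs(marker.freq)
                probs.append(((1 - marker.freq) ** 2, het, hom))
                xs.append((0.0, 1.0, entry.x_hom))
            mean_risk = 0.0
            for combo in itertools.product((0, 1, 2), repeat=8):
                w = math.prod(probs[i][g] for i, g in enumerate(combo))
                lp = b0 + sum(
                    model.coefficients[i].beta * xs[i][g] for i, g in enumerate(combo)
                )
                mean_risk += w * inverse_logit(lp)
            # Jensen lower bound and a rigorous second-order upper bound:
            # invlogit(t) <= invlogit(m) + invlogit'(m)(t-m) + 0.5*sup|f''|*(t-m)^2
            # with sup|f''| = 1/(6*sqrt(3)); take expectations over LP.
            sup_f2 = 1.0 / (6.0 * math.sqrt(3.0))
            assert mean_risk >= inverse_logit(mean_lp) - 1e-12
            assert mean_risk <= inverse_logit(mean_lp) + 0.5 * sup_f2 * var_lp
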