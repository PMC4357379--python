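"""Cohort statistics: correlation oracle, co-occurrence, survival machinery."""

import math

import numpy as np
import pytest

from umdpcr import (
    CohortSimConfig,
    SurvivalRecord,
    TumourProfile,
    cooccurrence,
    cox_hr,
    km_fit,
    logrank,
    platform_correlation,
    simulate_cohort,
    survival_report,
)
from umdpcr.cnv import Chr8Mechanism, TumourRecord


def pearson_brute_force(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ca, cb = a - a.mean(), b - b.mean()
    return float((ca * cb).sum() / math.sqrt((ca**2).sum() * (cb**2).sum()))


def two_group_logrank_oracle(times, events, groups):
    """Standardized observed-minus-expected, squared; hand-rolled from the
    risk-set definition, independent of lifelines."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        d = ((times == t) & (events == 1)).sum()
        n = at_risk.sum()
        n0 = (at_risk & (groups == g0)).sum()
        d0 = ((times == t) & (events == 1) & (groups == g0)).sum()
        e0 = d * n0 / n
        o_minus_e += d0 - e0
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def _profile(tid, chr3, q8):
    return TumourProfile(
        tumour_id=tid, chr3_status=chr3, cn_chr3=1.0 if chr3 == "monosomy" else 2.0,
        cn_8q=2.0, cn_8p=2.0, cn8q_class=q8, cn8p_class="normal",
        mechanism=Chr8Mechanism("no_aberration"),
        combined_group=f"{chr3}3+8q-{q8}", platform="dPCR")


class TestCorrelation:
    def test_identical_columns(self):
        recs = [TumourRecord(str(i), float(v), float(v), None, 2.0, 2.0,
                             2.0, 2.0, None)
                for i, v in enumerate((1.1, 1.9, 2.4, 3.3))]
        res = platform_correlation(recs, "snp", "dpcr", "chr3")
        assert res.r == pytest.approx(1.0)

    def test_matches_brute_force_on_fixture(self, cohort_records):
        res = platform_correlation(cohort_records, "snp", "dpcr", "8q")
        a = [r.snp_8q for r in cohort_records]
        b = [r.dpcr_8q for r in cohort_records]
        assert res.r == pytest.approx(pearson_brute_force(a, b), abs=1e-12)

    def test_karyotype_pairs_drop_missing(self, cohort_records):
        res = platform_correlation(cohort_records, "dpcr", "karyotype", "chr3")
        assert res.n == 66 - 15  # 15 tumours never karyotyped
        assert res.r > 0  # sign convention maps code 1 (monosomy) to low cn

    def test_zero_variance_rejected(self):
        recs = [TumourRecord(str(i), 2.0, float(i), None, 2.0, 2.0, 2.0, 2.0,
                             None) for i in range(5)]
        with pytest.raises(ValueError):
            platform_correlation(recs, "snp", "dpcr", "chr3")


class TestCooccurrence:
    def test_single_tumour_cohort(self):
        table = cooccurrence([_profile("t", "monosomy", "gain")])
        assert table.counts[("monosomy", "gain")] == 1
        assert sum(table.counts.values()) == 1

    def test_fixture_joint_distribution(self, cohort_profiles):
        table = cooccurrence(cohort_profiles)
        assert table.n_total == 66
        assert table.monosomy3_with_8q_aberration == 40
        assert table.monosomy3_with_normal_chr8 == 3
        assert table.disomy3_with_8q_aberration == 12
        assert table.margin_chr3("monosomy") == 43


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        recs = [SurvivalRecord("a", 1.0, True, "g"),
                SurvivalRecord("b", 2.0, True, "g"),
                SurvivalRecord("c", 3.0, False, "g")]
        fit = km_fit(recs)
        assert fit.survival_at("g", 1.0) == pytest.approx(2 / 3)
        assert fit.survival_at("g", 2.0) == pytest.approx(1 / 3)
        assert fit.survival_at("g", 3.0) == pytest.approx(1 / 3)
        assert fit.survival_at("g", 0.5) == pytest.approx(1.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(30, 50)
        recs = [SurvivalRecord(str(i), float(t), True, "g")
                for i, t in enumerate(times)]
        fit = km_fit(recs)
        for t in (5.0, 20.0, 60.0):
            assert fit.survival_at("g", t) == pytest.approx((times > t).mean())

    def test_curves_start_at_one_and_decrease(self):
        _, survival, _ = simulate_cohort(CohortSimConfig(n_tumours=200, seed=4))
        fit = km_fit(survival)
        for times, surv in fit.curves.values():
            assert surv[0] == pytest.approx(1.0)
            assert (np.diff(surv) <= 1e-12).all()

    def test_needs_an_event(self):
        recs = [SurvivalRecord("a", 5.0, False, "g")]
        with pytest.raises(ValueError):
            km_fit(recs)

    def test_calibration_three_classes(self):
        """At n=2000 the KM curves recover the configured 93/67/29%
        five-year survivals within 3 points."""
        mix = {("monosomy", "normal"): 1 / 3, ("monosomy", "gain"): 1 / 3,
               ("monosomy", "amplification"): 1 / 3}
        cfg = CohortSimConfig(n_tumours=2000, class_mix=mix, seed=12)
        _, survival, _ = simulate_cohort(cfg)
        fit = km_fit(survival)
        for group, s5 in (("normal", 0.93), ("gain", 0.67),
                          ("amplification", 0.29)):
            assert fit.survival_at(group, 60.0) == pytest.approx(s5, abs=0.03)


class TestLogrank:
    def _two_groups(self, seed=0, hr=1.0, n=120):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            recs.append(SurvivalRecord(f"a{i}", float(rng.exponential(50)),
                                       True, "A"))
            recs.append(SurvivalRecord(f"b{i}", float(rng.exponential(50 / hr)),
                                       True, "B"))
        return recs

    def test_matches_observed_expected_oracle(self):
        recs = self._two_groups(seed=3, hr=1.6, n=40)
        stat, p = logrank(recs)
        oracle = two_group_logrank_oracle(
            [r.months for r in recs], [r.event for r in recs],
            [r.group for r in recs])
        assert stat == pytest.approx(oracle, rel=1e-6)
        assert 0.0 <= p <= 1.0

    def test_label_swap_invariance(self):
        recs = self._two_groups(seed=5, hr=2.0, n=60)
        stat1, p1 = logrank(recs)
        swapped = [SurvivalRecord(r.tumour_id, r.months, r.event,
                                  "B" if r.group == "A" else "A")
                   for r in recs]
        stat2, p2 = logrank(swapped)
        assert stat1 == pytest.approx(stat2)
        assert p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([SurvivalRecord("a", 1.0, True, "g")])


class TestCox:
    def test_null_hazard_ratio_behaviour(self):
        """Identically generated groups: HR near 1, log-rank rarely
        significant."""
        ok_hr, ok_p, n_seeds = 0, 0, 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            recs = [SurvivalRecord(f"{g}{i}", float(rng.exponential(60)),
                                   True, g)
                    for g in ("A", "B") for i in range(200)]
            hrs = cox_hr(recs)
            hr = hrs["B_vs_A"][0]
            ok_hr += 0.7 <= hr <= 1.4
            _, p = logrank(recs)
            ok_p += p > 0.05
        assert ok_hr / n_seeds >= 0.9
        assert ok_p / n_seeds >= 0.9

    def test_recovers_simulated_log_hazard_ratio(self):
        """Mean log-HR over seeds within 5% of the simulated truth at
        n=2,000 per comparison."""
        true_hr = 2.0
        log_hrs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            recs = [SurvivalRecord(f"a{i}", float(rng.exponential(60)),
                                   True, "A") for i in range(1000)]
            recs += [SurvivalRecord(f"b{i}", float(rng.exponential(60 / true_hr)),
                                    True, "B") for i in range(1000)]
            log_hrs.append(math.log(cox_hr(recs)["B_vs_A"][0]))
        bias = abs(np.mean(log_hrs) - math.log(true_hr)) / math.log(true_hr)
        assert bias < 0.05

    def test_survival_report_bundle(self):
        _, survival, _ = simulate_cohort(CohortSimConfig(n_tumours=300, seed=2))
        rep = survival_report(survival)
        assert set(rep.curves) == {"normal", "gain", "amplification"}
        assert rep.logrank_p < 0.05  # classes are prognostically distinct
        for hr, lo, hi in rep.hazard_ratios.values():
            assert lo <= hr <= hi
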