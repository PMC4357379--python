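"""Droplet classification, Poisson estimation and aberrant-cluster scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from umdpcr import (
    ChannelThresholds,
    DropletCounts,
    DropletWell,
    WellSimConfig,
    classify_droplets,
    detect_aberrant_cluster,
    estimate_concentration,
    fit_thresholds,
    quantify_well,
    simulate_well,
)


def poisson_mle_grid(n_negative: int, n_total: int, lo=0.0, hi=8.0, step=1e-4):
    """Brute-force maximizer of the binomial log-likelihood over lambda.

    A droplet is negative with probability exp(-lambda); the grid search
    is independent of the closed-form estimator it checks.
    """
    lam = np.arange(lo + step, hi, step)
    p_neg = np.exp(-lam)
    ll = n_negative * np.log(p_neg) + (n_total - n_negative) * np.log1p(-p_neg)
    return float(lam[np.argmax(ll)])


class TestThresholds:
    def test_midpoint_of_two_point_clusters(self):
        amp = np.array([1000.0] * 50 + [5000.0] * 50)
        well = DropletWell("w", "a", amp, amp)
        thr = fit_thresholds(well)
        assert thr.channel1_cutoff == pytest.approx(3000.0)
        assert thr.channel2_cutoff == pytest.approx(3000.0)
        assert thr.method == "data-driven"

    def test_single_cluster_falls_back_above_negatives(self):
        rng = np.random.default_rng(0)
        neg = rng.normal(1000, 100, 5000)
        well = DropletWell("w", "a", neg, neg)
        thr = fit_thresholds(well)
        counts = classify_droplets(well, thr)
        assert counts.n_double_negative == counts.n_total
        assert thr.method == "fixed"

    def test_identical_amplitudes_fall_back(self):
        amp = np.full(200, 1000.0)
        thr = fit_thresholds(DropletWell("w", "a", amp, amp))
        assert thr.method == "fixed"

    def test_simulated_well_low_misclassification(self):
        cfg = WellSimConfig(n_droplets=20000, ch1_copies=10000, ch2_copies=10000,
                            seed=11)
        well, truth = simulate_well(cfg)
        thr = fit_thresholds(well)
        for channel, occupancy in ((1, truth.occupancy_ch1), (2, truth.occupancy_ch2)):
            predicted = well.amplitudes(channel) > thr.cutoff(channel)
            assert (predicted != (occupancy > 0)).mean() < 0.001


class TestClassification:
    def test_quadrant_example(self):
        well = DropletWell("w", "a",
                           np.array([100, 100, 5000, 5000, 5000.0]),
                           np.array([100.0] * 5))
        counts = classify_droplets(well, ChannelThresholds(2500, 2500))
        assert counts.n_ch1_only == 3
        assert counts.n_double_negative == 2
        assert counts.n_ch2_only == 0 and counts.n_double_positive == 0

    def test_all_above_both_cutoffs(self):
        amp = np.full(10, 9000.0)
        counts = classify_droplets(DropletWell("w", "a", amp, amp),
                                   ChannelThresholds(2500, 2500))
        assert counts.n_double_positive == counts.n_total == 10

    def test_droplet_at_cutoff_is_negative(self):
        well = DropletWell("w", "a", np.array([2500.0]), np.array([2500.1]))
        counts = classify_droplets(well, ChannelThresholds(2500, 2500))
        assert counts.n_ch2_only == 1

    @given(st.lists(st.floats(0, 10000, allow_nan=False), min_size=1, max_size=50),
           st.floats(0, 10000), st.floats(0, 10000))
    @settings(max_examples=50, deadline=None)
    def test_count_conservation(self, ch1, c1, c2):
        well = DropletWell("w", "a", np.array(ch1), np.array(ch1[::-1]))
        counts = classify_droplets(well, ChannelThresholds(c1, c2))
        total = (counts.n_double_negative + counts.n_ch1_only
                 + counts.n_ch2_only + counts.n_double_positive)
        assert total == counts.n_total == well.n_droplets

    def test_counts_validate(self):
        with pytest.raises(ValueError):
            DropletCounts(10, 5, 5, 5, 0)


class TestConcentration:
    def test_closed_form_half_negative(self):
        c = estimate_concentration(10000, 20000)
        assert c.lam == pytest.approx(math.log(2), rel=1e-12)
        assert c.ci_low < c.lam < c.ci_high
        assert c.copies_per_microliter == pytest.approx(c.lam / 0.85e-3)
        assert c.estimated_template_copies == pytest.approx(c.lam * 20000)

    def test_all_negative_is_zero(self):
        c = estimate_concentration(20000, 20000)
        assert c.lam == 0.0 and c.ci_low == 0.0 and not c.saturated

    def test_saturated_flagged_not_numeric(self):
        c = estimate_concentration(0, 20000)
        assert c.saturated and math.isnan(c.lam)

    def test_rejects_empty_well(self):
        with pytest.raises(ValueError):
            estimate_concentration(0, 0)

    @pytest.mark.parametrize("n_neg,n_total", [(1, 50), (10, 50), (25, 50),
                                               (49, 50), (3, 17)])
    def test_matches_brute_force_likelihood(self, n_neg, n_total):
        lam_hat = estimate_concentration(n_neg, n_total).lam
        assert lam_hat == pytest.approx(poisson_mle_grid(n_neg, n_total), abs=1e-4)

    def test_monotone_in_negative_count(self):
        lams = [estimate_concentration(k, 200).lam for k in range(1, 200)]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_coverage_and_bias_monte_carlo(self):
        """95% CI covers the true lambda in 93-97% of seeds; estimator unbiased.

        Negative counts are drawn directly from the binomial partition
        model, independent of the amplitude pipeline.
        """
        true_lam, n = 0.5, 20000
        rng = np.random.default_rng(2024)
        n_neg = rng.binomial(n, math.exp(-true_lam), size=500)
        estimates, covered = [], 0
        for k in n_neg:
            c = estimate_concentration(int(k), n)
            estimates.append(c.lam)
            covered += c.ci_low <= true_lam <= c.ci_high
        assert np.mean(estimates) == pytest.approx(true_lam, rel=0.005)
        assert 0.93 <= covered / 500 <= 0.97

    def test_dilution_linearity(self):
        """Halving template copies halves lambda-hat in expectation."""
        est = {}
        for copies in (8000, 4000):
            lams = []
            for seed in range(30):
                well, _ = simulate_well(WellSimConfig(
                    ch1_copies=copies, ch2_copies=0, seed=seed))
                lams.append(quantify_well(well).channel1.lam)
            est[copies] = np.mean(lams)
        assert est[8000] / est[4000] == pytest.approx(2.0, rel=0.02)


class TestAberrantCluster:
    def test_no_cross_reactivity_no_cluster(self):
        cfg = WellSimConfig.mutation_assay(10, 0.8, targets_mutant=False,
                                           cross_reactivity=0.0, seed=7)
        well, _ = simulate_well(cfg)
        q = quantify_well(well)
        assert not q.aberrant.detected

    def test_targeting_assay_has_no_cluster(self):
        cfg = WellSimConfig.mutation_assay(10, 0.8, targets_mutant=True, seed=7)
        well, _ = simulate_well(cfg)
        assert not quantify_well(well).aberrant.detected

    def test_occupancy_matches_truth(self):
        cfg = WellSimConfig.mutation_assay(10, 0.8, targets_mutant=False,
                                           cross_reactivity=0.5, seed=5)
        well, truth = simulate_well(cfg)
        rep = quantify_well(well).aberrant
        assert rep.detected
        true_frac = truth.fraction("aberrant")
        se = math.sqrt(true_frac * (1 - true_frac) / well.n_droplets)
        assert abs(rep.occupancy_fraction - true_frac) <= 3 * se + 1e-9

    def test_paired_assays_similar_occupancy(self):
        """Aberrant fraction in a non-targeting assay tracks the
        mutant-positive fraction of the targeting assay on the same sample."""
        occ_ab, occ_pos = [], []
        for seed in range(20):
            w_ab, _ = simulate_well(WellSimConfig.mutation_assay(
                10, 0.8, targets_mutant=False, cross_reactivity=0.5, seed=seed))
            w_pos, _ = simulate_well(WellSimConfig.mutation_assay(
                10, 0.8, targets_mutant=True, seed=1000 + seed))
            q_ab = quantify_well(w_ab)
            q_pos = quantify_well(w_pos)
            occ_ab.append(q_ab.aberrant.occupancy_fraction)
            occ_pos.append(q_pos.counts.n_positive(1) / w_pos.n_droplets)
        # The aberrant cluster misses mutant droplets that also hold WT
        # template (they saturate positive), a factor exp(-lambda_wt).
        lam_wt = 10 * (1000 / 3.3) * (1 - 0.8 / 2) / 20000
        assert np.mean(occ_ab) == pytest.approx(
            np.mean(occ_pos) * math.exp(-lam_wt), rel=0.05)

    def test_too_few_droplets_not_detected(self):
        rng = np.random.default_rng(3)
        ch2 = np.concatenate([rng.normal(1000, 100, 195),
                              rng.normal(3000, 100, 5)])
        well = DropletWell("w", "a", np.full(200, 1000.0), ch2)
        rep = detect_aberrant_cluster(well, ChannelThresholds(3000, 4000))
        assert not rep.detected
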