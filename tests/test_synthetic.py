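"""Synthetic-registry generator: censored draws, recovery curve, determinism,
and agreement with its own latent-truth channel."""

import math

import numpy as np
import pytest

from powergap import PromScale, SimConfig, generate_registry
from powergap.records import DistributionCode, RationaleCode, TrialRecord
from powergap.registry_io import record_to_row
from powergap.synthetic import (
    _RATIONALE_COUNTS,
    clipped_normal_moments,
    latent_mean_at,
    simulate_arm,
)


class TestSimulateArm:
    def test_midscale_mean_is_unbiased_when_clipping_negligible(self):
        rng = np.random.default_rng(0)
        scale = PromScale(0.0, 100.0)
        arm, ceiling_frac = simulate_arm(50.0, 10.0, 10_000, scale, rng)
        se = 10.0 / math.sqrt(10_000)
        assert abs(arm.mean - 50.0) < 3 * se
        assert ceiling_frac == pytest.approx(0.0, abs=1e-3)

    def test_latent_mean_at_best_score_puts_half_the_mass_at_the_ceiling(self):
        rng = np.random.default_rng(1)
        scale = PromScale(0.0, 100.0)
        _, ceiling_frac = simulate_arm(100.0, 15.0, 20_000, scale, rng)
        assert ceiling_frac == pytest.approx(0.5, abs=0.02)

    def test_degenerate_sigma_collapses_to_clipped_point(self):
        rng = np.random.default_rng(2)
        arm, _ = simulate_arm(120.0, 0.0, 50, PromScale(0.0, 100.0), rng)
        assert arm.mean == 100.0
        assert arm.sd == 0.0

    def test_reversed_scale_ceiling_is_the_low_bound(self):
        rng = np.random.default_rng(3)
        _, ceiling_frac = simulate_arm(0.0, 2.0, 20_000, PromScale(10.0, 0.0), rng)
        assert ceiling_frac == pytest.approx(0.5, abs=0.02)


class TestLatentMeanAt:
    scale = PromScale(0.0, 100.0)

    def test_initial_condition(self):
        assert latent_mean_at(0.0, self.scale, 0.5, 0.9, 120.0) == pytest.approx(50.0)

    def test_asymptote(self):
        assert latent_mean_at(1e9, self.scale, 0.5, 0.9, 120.0) == pytest.approx(90.0)

    def test_one_time_constant(self):
        # 0.9 - 0.4/e = 0.75285...
        expected = 100 * (0.9 - 0.4 * math.exp(-1.0))
        assert latent_mean_at(120.0, self.scale, 0.5, 0.9, 120.0) == pytest.approx(expected)

    def test_monotone_toward_ceiling(self):
        values = [latent_mean_at(t, self.scale, 0.4, 0.95, 100.0) for t in range(0, 2000, 50)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_reversed_scale_moves_down(self):
        pain = PromScale(10.0, 0.0)
        early = latent_mean_at(10.0, pain, 0.4, 0.9, 100.0)
        late = latent_mean_at(1000.0, pain, 0.4, 0.9, 100.0)
        assert late < early

    def test_bad_tau_rejected(self):
        with pytest.raises(ValueError):
            latent_mean_at(10.0, self.scale, 0.4, 0.9, 0.0)


class TestClippedNormalMoments:
    @pytest.mark.parametrize(
        "mu, sigma, lo, hi",
        [(50.0, 10.0, 0.0, 100.0), (95.0, 15.0, 0.0, 100.0), (110.0, 20.0, 0.0, 100.0),
         (2.0, 3.0, 0.0, 10.0)],
    )
    def test_against_monte_carlo(self, mu, sigma, lo, hi):
        rng = np.random.default_rng(99)
        draws = np.clip(rng.normal(mu, sigma, size=400_000), lo, hi)
        mean, sd = clipped_normal_moments(mu, sigma, lo, hi)
        assert mean == pytest.approx(draws.mean(), abs=4 * sd / math.sqrt(400_000) + 1e-3)
        assert sd == pytest.approx(draws.std(ddof=1), rel=0.01)

    def test_no_clipping_limit(self):
        mean, sd = clipped_normal_moments(50.0, 5.0, -1e9, 1e9)
        assert mean == pytest.approx(50.0)
        assert sd == pytest.approx(5.0)


class TestGenerateRegistry:
    def test_deterministic_under_seed(self):
        config = SimConfig(n_trials=60, seed=123)
        first = generate_registry(config)
        second = generate_registry(SimConfig(n_trials=60, seed=123))
        rows_a = [record_to_row(r) for r in first[0]]
        rows_b = [record_to_row(r) for r in second[0]]
        assert rows_a == rows_b
        assert first[1] == second[1]

    def test_different_seed_changes_registry(self):
        a, _ = generate_registry(SimConfig(n_trials=30, seed=1))
        b, _ = generate_registry(SimConfig(n_trials=30, seed=2))
        assert [record_to_row(r) for r in a] != [record_to_row(r) for r in b]

    def test_all_records_valid_and_counted(self, default_registry):
        records, truths = default_registry
        assert len(records) == 264
        assert len(truths) == 264
        assert all(isinstance(r, TrialRecord) and r.flags is not None for r in records)

    def test_missing_variability_fraction_matches_design(self, large_registry):
        records, _ = large_registry
        n = len(records)
        missing = sum(1 for r in records if not r.flags.has_outcome_summaries)
        p = SimConfig().missing_variability_fraction
        # binomial 3-sigma band around the configured missingness rate
        tol = 3 * math.sqrt(p * (1 - p) / n)
        assert abs(missing / n - p) < tol

    def test_md_est_inflated_above_latent_effect_on_average(self, default_registry):
        records, truths = default_registry
        inflations = np.array([t.inflation for t in truths])
        assert np.median(inflations) > 1.0
        by_id = {r.trial_id: r for r in records}
        for truth in truths[:50]:
            record = by_id[truth.trial_id]
            assert record.power.md_est == pytest.approx(
                truth.latent_delta * truth.inflation, rel=1e-9
            )

    def test_category_marginals_within_three_binomial_se(self, default_registry):
        records, _ = default_registry
        n = len(records)
        for code, count in _RATIONALE_COUNTS.items():
            p = count / 264
            observed = sum(
                1 for r in records if r.power and r.power.rationale is code
            )
            tol = 3 * math.sqrt(n * p * (1 - p)) + 1
            assert abs(observed - n * p) <= tol, code
        p_only = 209 / 264
        only = sum(
            1
            for r in records
            if r.distribution_codes == {DistributionCode.MEAN_MEDIAN_ONLY}
        )
        assert abs(only - n * p_only) <= 3 * math.sqrt(n * p_only * (1 - p_only)) + 1

    def test_mean_median_only_is_exclusive(self, large_registry):
        records, _ = large_registry
        for record in records:
            if DistributionCode.MEAN_MEDIAN_ONLY in record.distribution_codes:
                assert len(record.distribution_codes) == 1
            else:
                assert len(record.distribution_codes) >= 1

    def test_zero_trials_gives_empty_registry(self):
        records, truths = generate_registry(SimConfig(n_trials=0))
        assert records == [] and truths == []

    def test_invalid_config_named_explicitly(self):
        with pytest.raises(ValueError, match="followup_weights_prom"):
            SimConfig(followup_weights_prom=(1.0, 0.5, 0, 0, 0)).validate()
        with pytest.raises(ValueError, match="n_trials"):
            SimConfig(n_trials=-1).validate()


class TestNoAttenuationNull:
    def test_degenerate_inflation_and_no_censoring_centres_ratio_at_one(self):
        """With the MD estimate equal to the latent effect and clipping
        negligible (tight sigma, mid-scale means), the pipeline median ratio
        sits near 1."""
        from powergap import audit_registry

        config = SimConfig(
            n_trials=400,
            seed=5,
            inflation_log_mean=0.0,
            inflation_log_sd=0.0,
            b0_mean=0.5,
            b0_sd=0.01,
            b_inf_mean=0.55,
            b_inf_sd=0.01,
            sigma_frac_range=(0.05, 0.08),
            delta_over_sigma_mean=0.6,
            delta_over_sigma_sd=0.05,
            missing_variability_fraction=0.0,
            sd_est_fraction=1.0,
        )
        records, _ = generate_registry(config)
        result = audit_registry(records)
        median = float(np.nanmedian(result.per_trial["ratio"]))
        assert median == pytest.approx(1.0, abs=0.1)
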