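"""Calibration tests: data generation, quantile rule, robust procedure."""

import numpy as np
import pytest

from baskex import (
    CalibrationSpec,
    ExnexConfig,
    MCMCSettings,
    Scenario,
    TrialStructure,
    calibrate_approach,
    calibrate_global_null,
    generate_trial,
    global_null_spec,
    match_cutoff_by_sample_size,
    rcap_calibrate,
)
from baskex.calibration import _order_stat_quantile, generate_batch
from baskex.model import fit_exnex_batch

CAL_MCMC = MCMCSettings(n_chains=2, n_warmup=300, n_samples=700, seed=0)


class TestGenerateTrial:
    def test_degenerate_rates(self, rng):
        sc0 = Scenario(p=[0.0, 0.0], n=[10, 10])
        sc1 = Scenario(p=[1.0, 1.0], n=[10, 10])
        assert np.all(generate_trial(sc0, rng).y == 0)
        assert np.all(generate_trial(sc1, rng).y == np.array([10, 10]))

    def test_binomial_mean(self):
        sc = Scenario(p=[0.2, 0.4], n=[24, 24])
        Y = generate_batch(sc, 10_000, master_seed=5, key=0)
        se = np.sqrt(0.2 * 0.8 / 24 / 10_000)
        assert abs(Y[:, 0].mean() / 24 - 0.2) < 3 * se

    def test_replicates_are_replayable(self):
        sc = Scenario(p=[0.3, 0.3], n=[12, 12])
        a = generate_batch(sc, 50, master_seed=9, key=4)
        b = generate_batch(sc, 50, master_seed=9, key=4)
        np.testing.assert_array_equal(a, b)


class TestQuantileRule:
    def test_median_at_alpha_half(self):
        vals = np.array([0.1, 0.9, 0.5, 0.3, 0.7])
        assert _order_stat_quantile(vals, 0.5) == 0.5

    def test_order_statistic_no_interpolation(self):
        vals = np.linspace(0, 1, 10)
        # rank ceil(0.9 * 10) = 9 -> ninth order statistic
        assert _order_stat_quantile(vals, 0.10) == vals[8]


class TestMatchCutoff:
    def test_equal_sample_sizes_inherit_directly(self):
        assert match_cutoff_by_sample_size([0.86] * 4, [24] * 4, 14) == 0.86

    def test_nearest_sample_size_wins(self):
        assert match_cutoff_by_sample_size([0.1, 0.2, 0.3], [10, 20, 30], 22) == 0.2

    def test_tie_breaks_to_smallest_index(self):
        assert match_cutoff_by_sample_size([0.1, 0.3], [10, 30], 20) == 0.1

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            match_cutoff_by_sample_size([], [], 10)


class TestRobustCalibration:
    def test_single_scenario_equals_global_null(self, config):
        """The robust procedure with one all-null scenario is exactly the
        classical global-null calibration at matched seeds."""
        spec = global_null_spec([8, 8, 6], R=150, alpha=0.10, q0=0.2, seed=21)
        a = rcap_calibrate(spec, config, CAL_MCMC)
        b = calibrate_global_null(spec, config, CAL_MCMC)
        np.testing.assert_array_equal(a.delta_existing, b.delta_existing)

    def test_weight_replication_equivalence(self, config):
        """Integer weight w on a scenario is exactly equivalent to listing
        the scenario w times with a shared seed key."""
        s1 = Scenario(p=[0.2, 0.2, 0.2], n=[8, 8, 6], name="null", seed_key=0)
        s2 = Scenario(p=[0.4, 0.2, 0.2], n=[8, 8, 6], name="partial", seed_key=1)
        weighted = CalibrationSpec(
            scenarios=(Scenario(p=s1.p, n=s1.n, weight=2, seed_key=0), s2),
            R=120, alpha=0.10, q0=0.2, seed=33,
        )
        repeated = CalibrationSpec(
            scenarios=(s1, s1, s2), R=120, alpha=0.10, q0=0.2, seed=33
        )
        a = rcap_calibrate(weighted, config, CAL_MCMC)
        b = rcap_calibrate(repeated, config, CAL_MCMC)
        np.testing.assert_array_equal(a.delta_existing, b.delta_existing)

    def test_equal_sample_sizes_share_identical_cutoffs(self, config):
        spec = global_null_spec([8, 8, 6], R=150, alpha=0.10, q0=0.2, seed=2)
        cut = rcap_calibrate(spec, config, CAL_MCMC)
        assert cut.delta_existing[0] == cut.delta_existing[1]
        assert cut.delta_existing[0] != cut.delta_existing[2]

    def test_all_effective_scenarios_rejected(self, config):
        spec = CalibrationSpec(
            scenarios=(Scenario(p=[0.4, 0.4], n=[8, 8]),),
            R=50, alpha=0.10, q0=0.2, seed=3,
        )
        with pytest.raises(ValueError, match="null"):
            rcap_calibrate(spec, config, CAL_MCMC)

    def test_uncovered_sample_size_class_named_in_error(self, config):
        # only the n=8 baskets are ever null; the n=6 basket has no store
        spec = CalibrationSpec(
            scenarios=(Scenario(p=[0.2, 0.2, 0.4], n=[8, 8, 6]),),
            R=60, alpha=0.10, q0=0.2, seed=4,
        )
        with pytest.raises(ValueError, match="6"):
            rcap_calibrate(spec, config, CAL_MCMC)

    def test_more_effective_scenarios_weighted_up_never_lower_cutoffs(self, config):
        """Borrowing from effective baskets inflates null exceedance, so
        up-weighting scenarios with more effective baskets is conservative."""
        s_null = Scenario(p=[0.2, 0.2, 0.2], n=[8, 8, 6], seed_key=0)
        s_eff = Scenario(p=[0.4, 0.4, 0.2], n=[8, 8, 6], seed_key=1)

        def run(w_eff):
            spec = CalibrationSpec(
                scenarios=(s_null, Scenario(p=s_eff.p, n=s_eff.n, weight=w_eff, seed_key=1)),
                R=200, alpha=0.10, q0=0.2, seed=8,
            )
            return rcap_calibrate(spec, config, CAL_MCMC).delta_existing

        assert np.all(run(4) >= run(1))

    def test_level_property(self, config):
        """Replaying the calibration scenarios against the calibrated
        cut-offs recovers the nominal level on (weighted) average."""
        scenarios = (
            Scenario(p=[0.2, 0.2, 0.2], n=[8, 8, 6], seed_key=0),
            Scenario(p=[0.4, 0.2, 0.2], n=[8, 8, 6], seed_key=1),
        )
        alpha, R_cal, R_eval = 0.15, 400, 400
        spec = CalibrationSpec(scenarios=scenarios, R=R_cal, alpha=alpha, q0=0.2, seed=5)
        cut = rcap_calibrate(spec, config, CAL_MCMC)
        hits = total = 0
        for sc in scenarios:
            Y = generate_batch(sc, R_eval, master_seed=99, key=sc.seed_key)
            bp = fit_exnex_batch(Y, sc.n, config, MCMCSettings(2, 300, 700, seed=42))
            null = np.flatnonzero(sc.p == 0.2)
            rej = bp.exceed_prob[:, null] > cut.delta_existing[null][None, :]
            hits += rej.sum()
            total += rej.size
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert abs(hits / total - alpha) < 3 * se


class TestCalibrateApproach:
    SCEN = [
        Scenario(p=[0.2, 0.2, 0.2], n=[8, 8, 6], seed_key=0),
        Scenario(p=[0.4, 0.2, 0.2], n=[8, 8, 6], seed_key=1),
    ]

    def test_pl2a_existing_matches_ind_existing(self, config, tiny_structure):
        kw = dict(weights=None, R=100, alpha=0.1, config=config, mcmc=CAL_MCMC, method="rcap")
        a = calibrate_approach("ind", tiny_structure, self.SCEN, **kw)
        b = calibrate_approach("pl2a", tiny_structure, self.SCEN, **kw)
        np.testing.assert_array_equal(a.delta_existing, b.delta_existing)

    def test_unpl_inherits_existing_cutoff(self, config, tiny_structure):
        cut = calibrate_approach(
            "unpl", tiny_structure, self.SCEN, None, 100, 0.1, config, CAL_MCMC, "rcap"
        )
        assert cut.delta_new[0] == cut.delta_existing[0]

    def test_pl1a_distinct_cutoff_per_sample_size(self, config, tiny_structure):
        cut = calibrate_approach(
            "pl1a", tiny_structure, None, None, 150, 0.1, config, CAL_MCMC, "global_null"
        )
        assert cut.delta_existing[0] == cut.delta_existing[1]
        assert cut.delta_new[0] != cut.delta_existing[0]

    def test_rcap_without_scenarios_errors(self, config, tiny_structure):
        with pytest.raises(ValueError):
            calibrate_approach(
                "ind", tiny_structure, None, None, 100, 0.1, config, CAL_MCMC, "rcap"
            )
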