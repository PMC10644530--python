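"""Ensembles, sweep aggregation, correlations, and tail-shape fitting."""

import numpy as np
import pandas as pd
import pytest

from genebirth import (
    CHLAMYDOMONAS,
    DFEParams,
    SimConfig,
    conducivity,
    fit_delta_A_shape,
    loss_classification,
    rare_jump_scenario,
    run_ensemble,
    run_sweep,
    sweep_correlations,
    trajectory_driver_correlations,
    trajectory_summary,
)
from genebirth.experiments import _pearson
from genebirth.population import ReplicateResult


def _stub_replicate(crossed, retained=True, mean_F=None):
    mean_F = np.asarray([0.0, -0.1, 0.2] if mean_F is None else mean_F, dtype=float)
    return ReplicateResult(
        crossed=crossed,
        retained=retained,
        extinct=False,
        crossed_ever=crossed,
        lca=None,
        seed=0,
        n_steps=mean_F.size - 1,
        mean_F=mean_F,
        sd_F=None,
        mean_E=None,
        mean_A=None,
        n_carriers=np.full(mean_F.size, 10),
    )


class TestConducivity:
    def test_boundary_is_conducive_at_half(self):
        results = [_stub_replicate(i < 50) for i in range(100)]
        frac, flag = conducivity(results)
        assert frac == 0.5 and flag

    def test_just_below_half_is_not(self):
        results = [_stub_replicate(i < 49) for i in range(100)]
        frac, flag = conducivity(results)
        assert frac == 0.49 and not flag

    def test_zero(self):
        frac, flag = conducivity([_stub_replicate(False)] * 10)
        assert frac == 0.0 and not flag

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            conducivity([])


class TestTrajectorySummary:
    def test_increasing_trajectory(self):
        r = _stub_replicate(True, mean_F=np.linspace(0, 1, 20))
        assert trajectory_summary(r) == (0.0, 0)

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(25):
            traj = rng.normal(0, 1, 50)
            r = _stub_replicate(True, mean_F=traj)
            mn, tmin = trajectory_summary(r)
            best_val, best_t = np.inf, -1
            for t, v in enumerate(traj):  # brute-force scan, first index on ties
                if v < best_val:
                    best_val, best_t = v, t
            assert (mn, tmin) == (best_val, best_t)


class TestEnsembles:
    def test_single_replicate_reproducible(self):
        config = SimConfig(N=40, T=40)
        r1 = run_ensemble(CHLAMYDOMONAS, config, 1, seed_base=7)
        r2 = run_ensemble(CHLAMYDOMONAS, config, 1, seed_base=7)
        np.testing.assert_array_equal(r1[0].mean_F, r2[0].mean_F)

    def test_replicates_match_partial_runs(self):
        config = SimConfig(N=30, T=30)
        full = run_ensemble(CHLAMYDOMONAS, config, 4, seed_base=3)
        part = run_ensemble(CHLAMYDOMONAS, config, 2, seed_base=3)
        for a, b in zip(part, full[:2]):
            np.testing.assert_array_equal(a.mean_F, b.mean_F)

    def test_pure_beneficial_dfe_always_adapts(self):
        # f = 1 with large p: fitness climbs ~p per step, crossing 0.1 fast
        dfe = DFEParams(p=0.005, f=1.0, n=0.001, s=0.9)
        config = SimConfig(N=100, T=300)
        frac, flag = conducivity(run_ensemble(dfe, config, 5, seed_base=1))
        assert frac == 1.0 and flag


class TestSweepMachinery:
    def test_sweep_rows_and_determinism(self):
        grid_small = type(
            "G", (), dict(dfe_sets=(CHLAMYDOMONAS, DFEParams(0.005, 1.0, 0.001, 0.9)),
                          deletion_probs=(0.0, 1.0), population_size=40),
        )
        config = SimConfig(N=40, T=30)
        s1 = run_sweep(grid_small, config, 3, seed_base=5)
        s2 = run_sweep(grid_small, config, 3, seed_base=5)
        pd.testing.assert_frame_equal(s1, s2)
        assert len(s1) == 4
        # certain deletion: locus always lost, never conducive
        d1 = s1[s1.d == 1.0]
        assert (d1.loss_fraction == 1.0).all() and (d1.conducivity == 0.0).all()

    def test_loss_classification_rules(self):
        sweep = pd.DataFrame(
            {
                "conducivity_ever": [0.9, 0.9, 0.4, 0.51],
                "loss_fraction": [0.99, 0.5, 0.99, 0.96],
            }
        )
        got = loss_classification(sweep)
        assert list(got) == [
            "crossed-then-lost",
            "retained-conducive",
            "not-crossed",
            "crossed-then-lost",
        ]


class TestCorrelations:
    def test_perfect_linear_pair(self):
        r, p = _pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        r, _ = _pearson([1, 2, 3, 4], [-2, -4, -6, -8])
        assert r == pytest.approx(-1.0)

    def test_textbook_covariance_formula(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r, _ = _pearson(x, y)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected)

    def test_constant_vector_reported_missing(self):
        r, p = _pearson([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)

    def test_sweep_correlations_keys(self):
        sweep = pd.DataFrame(
            {
                "dfe_index": [0, 1, 2],
                "conducivity": [0.1, 0.5, 0.9],
                "mean_min_fitness": [-0.3, -0.2, -0.1],
                "mean_time_of_min": [300.0, 200.0, 100.0],
            }
        )
        out = sweep_correlations(sweep)
        r, _ = out["min_fitness_vs_time_of_min"]
        assert r == pytest.approx(-1.0)


class TestTailShapeFitting:
    def test_exponential_roundtrip(self, rng):
        rate = 3.7
        x = rng.exponential(1.0 / rate, 200_000)
        fit = fit_delta_A_shape(x)
        assert fit.law == "exponential"
        # rate is refit above the tail threshold; memorylessness keeps it equal
        assert fit.exponential_rate == pytest.approx(rate, rel=0.05)

    def test_powerlaw_roundtrip(self, rng):
        alpha = 2.5
        x = 1e-3 * (1.0 - rng.random(200_000)) ** (-1.0 / (alpha - 1.0))
        fit = fit_delta_A_shape(x)
        assert fit.law == "power-law"
        assert fit.powerlaw_exponent == pytest.approx(alpha, rel=0.05)

    def test_too_few_samples_declined(self, rng):
        with pytest.raises(ValueError):
            fit_delta_A_shape(rng.exponential(1.0, 50))


class TestDriverCorrelations:
    def test_proportional_trajectories(self):
        r = _stub_replicate(True, mean_F=np.linspace(0, 1, 30))
        r.mean_E = np.full(30, 0.5) + np.linspace(0, 0.1, 30)
        r.mean_A = 2.0 * r.mean_F
        corr_E, corr_A = trajectory_driver_correlations(r)
        assert corr_A == pytest.approx(1.0)
        assert corr_E == pytest.approx(1.0)

    def test_untracked_replicate_rejected(self):
        with pytest.raises(ValueError):
            trajectory_driver_correlations(_stub_replicate(True))


class TestRareJumpScenario:
    def test_certain_jumps_cross_quickly(self):
        # T >> N so the population coalesces and the fixed variant,
        # climbing +0.15 per step, is far above the threshold
        config = SimConfig(N=20, T=150, regime="high")
        frac = rare_jump_scenario(config, 3, seed_base=2, jump_prob=1.0)
        assert frac == 1.0

    def test_zero_jump_probability_reduces_to_base_dfe(self):
        # the base DFE is non-conducive; without jumps nothing crosses
        config = SimConfig(N=100, T=200, regime="high")
        frac = rare_jump_scenario(config, 4, seed_base=2, jump_prob=0.0)
        assert frac == 0.0

    def test_low_regime_rejected(self):
        with pytest.raises(ValueError):
            rare_jump_scenario(SimConfig(regime="low"), 1, 0)
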