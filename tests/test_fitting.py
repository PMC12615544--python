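"""Order-constrained fitting: exact optimality, Monte Carlo convergence,
adjusted R² arithmetic, and parameter recovery."""

import math
import warnings

import numpy as np
import pytest

import frontload as fl
from frontload.models import ModelName

from conftest import grid_search_sse, make_cells, point_mass_distribution


@pytest.fixture(scope="module")
def fast_pre():
    return fl.build_model(ModelName.FAST_PRECRASTINATION)


@pytest.fixture(scope="module")
def fast_proc():
    return fl.build_model(ModelName.FAST_PROCRASTINATION)


class TestFitExact:
    def test_noiseless_generative_identity(self, noiseless_records, fast_pre):
        filtered, _ = fl.filter_trials(noiseless_records)
        cm = fl.cell_means(filtered)["S001"]
        fr = fl.fit_exact(cm, fast_pre)
        assert fr.level_time_estimates == pytest.approx((1.0, 2.0, 3.0))
        assert fr.sse == pytest.approx(0.0, abs=1e-24)
        assert fr.r2 == pytest.approx(1.0)
        assert fr.adjusted_r2 == pytest.approx(1.0)
        assert fr.n_cells_used == 36

    def test_unconstrained_solution_already_monotone(self, fast_proc):
        means = np.full((6, 6), 0.70)
        means[fast_proc.levels == 3] = 1.10
        fr = fl.fit_exact(make_cells(means), fast_proc)
        t1, t2, t3 = fr.level_time_estimates
        assert (t1, t3) == pytest.approx((0.70, 1.10))
        assert math.isnan(t2)

    def test_order_violation_pools_groups(self, fast_proc):
        """When the unprepared cells average below the prepared cells, the
        constrained optimum shares one pooled mean, matching the
        brute-force grid oracle."""
        means = np.full((6, 6), 0.90)
        means[fast_proc.levels == 3] = 0.60  # violates level 1 <= level 3
        cm = make_cells(means)
        fr = fl.fit_exact(cm, fast_proc)
        t1, _, t3 = fr.level_time_estimates
        assert t1 == pytest.approx(t3)
        pooled = np.mean(means)
        assert t1 == pytest.approx(pooled)
        oracle = grid_search_sse(means.ravel(), fast_proc.levels.ravel())
        assert fr.sse <= oracle + 1e-9
        assert fr.sse == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("name", list(ModelName))
    def test_never_beaten_by_grid_oracle(self, name):
        """50 random cell matrices per model: the closed-form constrained
        minimum is at least as good as exhaustive 1-mm grid search."""
        model = fl.build_model(name)
        rng = np.random.default_rng(17)
        for _ in range(50):
            means = rng.uniform(0.3, 1.4, size=(6, 6))
            fr = fl.fit_exact(make_cells(means), model)
            oracle = grid_search_sse(means.ravel(), model.levels.ravel())
            assert fr.sse <= oracle + 1e-9

    def test_missing_level_rejected_by_name(self, fast_pre):
        means = np.full((6, 6), 0.7)
        means[0, 0] = np.nan  # the only level-3 cell of this model
        with pytest.raises(ValueError, match="level 3"):
            fl.fit_exact(make_cells(means), fast_pre)

    def test_weighted_fit_uses_counts(self, fast_proc):
        """With unequal counts the weighted level estimate is the
        count-weighted mean of its cells."""
        means = np.full((6, 6), 0.70)
        means[fast_proc.levels == 3] = [1.0, 1.0, 1.0, 1.0, 1.0, 1.6]
        counts = np.full((6, 6), 10)
        counts[5, 5] = 2  # downweight the 1.6-s cell
        fr_w = fl.fit_exact(make_cells(means, counts), fast_proc, weighted=True)
        expected = (5 * 10 * 1.0 + 2 * 1.6) / 52
        assert fr_w.level_time_estimates[2] == pytest.approx(expected)
        fr_u = fl.fit_exact(make_cells(means, counts), fast_proc, weighted=False)
        assert fr_u.level_time_estimates[2] == pytest.approx(np.mean([1.0] * 5 + [1.6]))

    def test_nesting_three_level_never_worse(self):
        """The three-level model's constrained SSE never exceeds the
        two-level pre-crastination model's (it can reproduce it by setting
        t2 = t3)."""
        rng = np.random.default_rng(3)
        spre = fl.build_model(ModelName.SLOW_PRECRASTINATION)
        fpre = fl.build_model(ModelName.FAST_PRECRASTINATION)
        for _ in range(25):
            means = rng.uniform(0.3, 1.5, size=(6, 6))
            cm = make_cells(means)
            assert fl.fit_exact(cm, fpre).sse <= fl.fit_exact(cm, spre).sse + 1e-12


class TestFitMonteCarlo:
    def test_never_beats_exact(self, default_subject_cells):
        for name in ModelName:
            model = fl.build_model(name)
            exact = fl.fit_exact(default_subject_cells, model)
            mc = fl.fit_monte_carlo(default_subject_cells, model, n_draws=2000, rng=1)
            assert mc.sse >= exact.sse - 1e-12

    def test_seeded_determinism(self, default_subject_cells, fast_pre):
        a = fl.fit_monte_carlo(default_subject_cells, fast_pre, n_draws=500, rng=8)
        b = fl.fit_monte_carlo(default_subject_cells, fast_pre, n_draws=500, rng=8)
        assert a == b

    def test_engine_labels(self, default_subject_cells, fast_pre):
        assert fl.fit_exact(default_subject_cells, fast_pre).engine is fl.Engine.EXACT
        mc = fl.fit_monte_carlo(default_subject_cells, fast_pre, n_draws=10, rng=0)
        assert mc.engine is fl.Engine.MONTE_CARLO


class TestAdjustedR2:
    def test_perfect_fit_is_one_regardless_of_p(self):
        assert fl.adjusted_r2(0.0, 1.0, 36, 2) == 1.0
        assert fl.adjusted_r2(0.0, 1.0, 36, 3) == 1.0

    def test_direct_arithmetic(self):
        assert fl.adjusted_r2(1.0, 1.0, 36, 2) == pytest.approx(1 - 35 / 33)

    def test_extra_parameter_penalized(self):
        assert fl.adjusted_r2(0.4, 1.0, 36, 3) < fl.adjusted_r2(0.4, 1.0, 36, 2)

    def test_constant_data_undefined(self):
        with pytest.warns(UserWarning, match="sst"):
            assert math.isnan(fl.adjusted_r2(0.0, 0.0, 36, 2))

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            fl.adjusted_r2(0.1, 1.0, 3, 2)


def test_parameter_recovery_within_noise_floor():
    """Data generated from each model at 0.05-s trial noise and 10 reps
    per condition: the exact fit under the generating model recovers each
    used level time within 0.05 s for >= 95% of 200 subjects."""
    dist = point_mass_distribution(level_times=(0.67, 0.79, 1.23), noise_sd=0.05)
    cfg = fl.ExperimentConfig(
        n_subjects=200, seed=21, subject_param_distribution=dist,
        generating_model=ModelName.FAST_PRECRASTINATION,
    )
    filtered, _ = fl.filter_trials(fl.simulate_experiment(cfg))
    cells = fl.cell_means(filtered)
    model = fl.build_model(ModelName.FAST_PRECRASTINATION)
    hits = 0
    for cm in cells.values():
        est = fl.fit_exact(cm, model).level_time_estimates
        if max(abs(e - t) for e, t in zip(est, (0.67, 0.79, 1.23))) <= 0.05:
            hits += 1
    assert hits / len(cells) >= 0.95
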