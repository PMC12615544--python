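import numpy as np
import pytest
from hypothesis import settings

import frontload as fl
from frontload.preprocessing import CellMeans

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_cells(means, counts=None, subject_id="X", full_preview=False) -> CellMeans:
    """Build a CellMeans directly from a matrix (counts default to 9)."""
    means = np.asarray(means, float).copy()
    if counts is None:
        counts = np.where(np.isfinite(means), 9, 0)
    return CellMeans(
        subject_id=subject_id,
        means=means,
        counts=np.asarray(counts, int).copy(),
        full_preview=full_preview,
    )


def point_mass_distribution(
    level_times=(0.67, 0.79, 1.23),
    noise_sd=0.0,
    outlier_prob=0.0,
    preview_base=3.1,
    preview_delta=0.5,
    preview_sd=0.0,
) -> fl.SubjectDistribution:
    """A degenerate population: every subject gets exactly these params."""
    F = fl.FieldDist
    return fl.SubjectDistribution(
        level_time_1=F(level_times[0]),
        level_time_2=F(level_times[1]),
        level_time_3=F(level_times[2]),
        noise_sd=F(noise_sd),
        outlier_prob=F(outlier_prob),
        preview_base=F(preview_base),
        preview_first_missing_delta=F(preview_delta),
        preview_sd=F(preview_sd),
    )


def grid_search_sse(cell_values, cell_levels, step=1e-3):
    """Independent brute-force oracle for the order-constrained SSE.

    Evaluates the objective on the full cartesian grid of level times in
    [0, max(cell_values)] at the given step, subject to ascending order
    across the model's used levels. The minimum over the ordered grid is
    computed exactly via running prefix minima (equivalent to enumerating
    every ordered tuple), independent of the fitting module's projection.
    """
    cell_values = np.asarray(cell_values, float)
    cell_levels = np.asarray(cell_levels)
    grid = np.arange(0.0, cell_values.max() + step, step)
    acc = None
    for level in sorted(set(cell_levels.tolist())):
        x = cell_values[cell_levels == level]
        cost = ((x[None, :] - grid[:, None]) ** 2).sum(axis=1)
        acc = cost if acc is None else np.minimum.accumulate(acc) + cost
    return float(acc.min())


@pytest.fixture(scope="session")
def default_subject_cells() -> CellMeans:
    """Cell means of one subject simulated under the default config."""
    cfg = fl.ExperimentConfig(n_subjects=1, seed=1)
    records = fl.simulate_experiment(cfg)
    filtered, _ = fl.filter_trials(records)
    return fl.cell_means(filtered)["S001"]


@pytest.fixture(scope="session")
def noiseless_records():
    """Deterministic trials generated without noise or outliers under the
    fast pre-crastination model with level times (1, 2, 3)."""
    cfg = fl.ExperimentConfig(
        n_subjects=1,
        seed=5,
        subject_param_distribution=point_mass_distribution(level_times=(1, 2, 3)),
    )
    return fl.simulate_experiment(cfg)
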