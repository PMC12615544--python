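"""Shared cohort definitions for the numbered analysis scripts.

Three simulated cohorts mirror the study design: two withheld-target
experiments (40 and 38 subjects) generated under the fast pre-crastination
model, and one full-preview experiment (35 subjects) with a longer mean
preview, as observed when every target is shown.
"""

from pathlib import Path

import frontload as fl

RESULTS = Path(__file__).resolve().parent.parent / "results"

BASE_SEED = 20260930


def cohort_configs() -> dict[str, fl.ExperimentConfig]:
    full_preview_dist = fl.SubjectDistribution(preview_base=fl.FieldDist(4.1, 1.2))
    return {
        "exp1": fl.ExperimentConfig(
            n_subjects=40, seed=BASE_SEED + 1, subject_prefix="E1S"
        ),
        "exp2": fl.ExperimentConfig(
            n_subjects=38, seed=BASE_SEED + 2, subject_prefix="E2S"
        ),
        "exp3": fl.ExperimentConfig(
            n_subjects=35,
            seed=BASE_SEED + 3,
            mode=fl.Mode.FULL_PREVIEW,
            subject_param_distribution=full_preview_dist,
            subject_prefix="E3S",
        ),
    }


def load_trials(name: str):
    from frontload.io import trials_from_csv

    path = RESULTS / name / "trials.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run analysis/01_simulate.py first")
    return trials_from_csv(path)
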