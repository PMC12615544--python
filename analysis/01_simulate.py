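"""Stage 1: simulate the three cohorts and write their trial logs.

Two withheld-target cohorts (40 and 38 subjects, every condition ten
times in random order) and one full-preview cohort (35 subjects) are
generated under the fast pre-crastination model with default population
parameters. Each cohort's trials and config land in results/<cohort>/.
"""

from _cohorts import RESULTS, cohort_configs

import frontload as fl
from frontload.io import trials_to_csv, write_config


def main() -> None:
    for name, cfg in cohort_configs().items():
        out = RESULTS / name
        out.mkdir(parents=True, exist_ok=True)
        records = fl.simulate_experiment(cfg)
        trials_to_csv(records, out / "trials.csv")
        write_config(cfg, out / "config.json")
        n_long = sum(t > 3 for r in records for t in r.response_times)
        print(
            f"{name}: {cfg.n_subjects} subjects x {cfg.n_trials} trials "
            f"({cfg.mode.value}); {n_long} response times exceed 3 s "
            f"({n_long / (len(records) * 6):.2%})"
        )


if __name__ == "__main__":
    main()
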