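"""Stage 4: pick each subject's winning model and test the group pattern.

Winners are the models with the largest adjusted R2 per subject; the
chance probability of the top model's count is the exact binomial point
mass at 1/4. The stage also runs the paired one-tailed contrasts the
winning model predicts for T1.
"""

import json

from _cohorts import RESULTS, load_trials

import frontload as fl
from frontload.report import mean_t2_t6, t1_certain, t1_uncertain


def main() -> None:
    for name in ("exp1", "exp2"):
        records = load_trials(name)
        filtered, _ = fl.filter_trials(records)
        cells = fl.cell_means(filtered)
        fits = fl.fit_all_models(cells, fl.all_models())
        sel = fl.select_model(fits)
        print(
            f"{name}: {sel.top_model.value} wins {sel.k_top}/{sel.n_subjects} "
            f"subjects (chance point p = {sel.binomial_point_p:.4e}, "
            f"tail p = {sel.binomial_tail_p:.4e})"
        )

        sids = sorted(cells)
        unc = [t1_uncertain(cells[s]) for s in sids]
        cer = [t1_certain(cells[s]) for s in sids]
        rest = [mean_t2_t6(cells[s]) for s in sids]
        contrasts = {
            "t1_uncertain_vs_certain": fl.paired_t_one_tailed(unc, cer, "greater"),
            "t1_uncertain_vs_t2_t6": fl.paired_t_one_tailed(unc, rest, "greater"),
            "t1_certain_vs_t2_t6": fl.paired_t_one_tailed(cer, rest, "greater"),
        }
        payload = {"selection": sel.counts}
        for label, res in contrasts.items():
            print(
                f"  {label}: t({res.df:.0f}) = {res.statistic:.2f}, "
                f"one-tailed p = {res.p_value:.2e}, d_rm = {res.effect_size:.2f}"
            )
            payload[label] = res.__dict__ | {"tails": res.tails.value}
        (RESULTS / name / "selection.json").write_text(
            json.dumps(payload, indent=2, default=str) + "\n"
        )


if __name__ == "__main__":
    main()
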