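"""Stage 5: the full-preview cohort — does T1 still stand out?

With no withheld target there is nothing to plan after the preview, so
the first response should no longer be lengthened. A one-way
repeated-measures ANOVA over response number, Bonferroni pairwise
follow-ups, and a directional test of T1 against the mean of T2-T6.
"""

import json

import numpy as np

from _cohorts import RESULTS, load_trials

import frontload as fl


def main() -> None:
    records = load_trials("exp3")
    filtered, _ = fl.filter_trials(records)
    cells = fl.cell_means(filtered)
    matrix = np.stack([cells[s].means[0] for s in sorted(cells)])
    print("mean times T1..T6:", np.round(matrix.mean(axis=0), 3))

    omnibus, pairwise = fl.rm_anova(matrix)
    k = matrix.shape[1]
    print(
        f"response-number ANOVA: F({k - 1},{omnibus.df:.0f}) = "
        f"{omnibus.statistic:.2f}, p = {omnibus.p_value:.3e}"
    )
    t1_rows = pairwise[pairwise["condition_a"] == 1]
    print(
        "largest Bonferroni p for T1 vs others:",
        f"{t1_rows['p_bonferroni'].max():.4f}",
    )

    res = fl.paired_t_one_tailed(
        matrix[:, 0], matrix[:, 1:].mean(axis=1), "less"
    )
    print(
        f"T1 < mean(T2-T6): t({res.df:.0f}) = {res.statistic:.2f}, "
        f"one-tailed p = {res.p_value:.4f}, d_rm = {res.effect_size:.2f}"
    )

    out = RESULTS / "exp3"
    pairwise.to_csv(out / "pairwise_bonferroni.csv", index=False)
    (out / "anova.json").write_text(
        json.dumps(
            {
                "F": omnibus.statistic,
                "df_condition": k - 1,
                "df_error": omnibus.df,
                "p": omnibus.p_value,
                "partial_eta_sq": omnibus.effect_size,
                "t1_vs_rest_t": res.statistic,
                "t1_vs_rest_p": res.p_value,
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    main()
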