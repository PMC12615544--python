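"""Stage 6: preview-time analyses.

Within each withheld-target cohort: are previews shorter when target 1 is
the one withheld (nothing about it can be prepared in advance, so the
preview can end sooner)? Across cohorts: are previews longer when all six
targets are shown (extra motor preparation), via Welch's t on the
full-preview cohort against the pooled withheld-target cohorts.
"""

import json

import numpy as np

from _cohorts import RESULTS, load_trials

import frontload as fl


def _subject_previews(records, condition=None):
    by_subject = {}
    for r in records:
        if r.trial_index <= 6:
            continue
        if condition == "first" and r.missing_target != 1:
            continue
        if condition == "later" and r.missing_target in (1, None):
            continue
        by_subject.setdefault(r.subject_id, []).append(r.preview_time)
    return {s: float(np.mean(v)) for s, v in sorted(by_subject.items())}


def main() -> None:
    pooled = []
    for name in ("exp1", "exp2"):
        records = load_trials(name)
        first = _subject_previews(records, "first")
        later = _subject_previews(records, "later")
        sids = sorted(first)
        res = fl.paired_t_one_tailed(
            [first[s] for s in sids], [later[s] for s in sids], "less"
        )
        print(
            f"{name}: preview with target 1 withheld "
            f"{np.mean(list(first.values())):.2f} s vs later target "
            f"{np.mean(list(later.values())):.2f} s; one-tailed "
            f"t({res.df:.0f}) = {res.statistic:.2f}, p = {res.p_value:.4f}, "
            f"d_rm = {res.effect_size:.2f}"
        )
        pooled.extend(_subject_previews(records).values())

    full = list(_subject_previews(load_trials("exp3")).values())
    welch = fl.welch_t(np.array(full), np.array(pooled))
    print(
        f"full preview vs pooled withheld: M = {np.mean(full):.2f} s "
        f"(n={len(full)}) vs {np.mean(pooled):.2f} s (n={len(pooled)}); "
        f"Welch t = {welch.statistic:.2f}, df = {welch.df:.1f}, "
        f"p = {welch.p_value:.3f}, d_pooled = {welch.effect_size:.2f}"
    )
    (RESULTS / "preview_comparison.json").write_text(
        json.dumps(
            {
                "welch_t": welch.statistic,
                "df": welch.df,
                "p": welch.p_value,
                "d_pooled": welch.effect_size,
                "mean_full_preview": float(np.mean(full)),
                "mean_withheld_pooled": float(np.mean(pooled)),
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    main()
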