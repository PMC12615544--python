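"""End-to-end study orchestration: simulate, filter, fit, select, report.

``run_study`` composes the pipeline stages into a single JSON-ready
report (and optionally writes the trial log, cell means, fits, report and
summary figures to disk); ``compare_experiments`` pools preview times
across studies and contrasts them with Welch's t, mirroring the
full-preview vs withheld-target comparison.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as fio
from .fitting import DEFAULT_MC_DRAWS, Engine, fit_all_models, fits_to_csv
from .inference import (
    SelectionResult,
    TestResult,
    paired_t_one_tailed,
    rm_anova,
    select_model,
    welch_t,
)
from .models import all_models
from .preprocessing import (
    DEFAULT_CUTOFF,
    CellMeans,
    cell_means,
    cell_means_to_csv,
    filter_trials,
    grand_cell_means,
)
from .synthetic import (
    ExperimentConfig,
    Mode,
    TrialRecord,
    config_from_dict,
    config_to_dict,
    simulate_experiment,
)

__all__ = [
    "run_study",
    "compare_experiments",
    "validate_report",
    "format_report_text",
    "SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_REQUIRED_KEYS = {
    "schema_version",
    "config",
    "filter_report",
    "group_curves",
    "fit_summary",
    "selection",
    "tests",
    "preview",
}


def _jsonable(obj):
    """Recursively convert to JSON-safe types; NaN/inf become null."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def _test_to_dict(t: TestResult) -> dict:
    return {
        "statistic": t.statistic,
        "df": t.df,
        "p_value": t.p_value,
        "effect_size": t.effect_size,
        "tails": t.tails.value,
    }


def _selection_to_dict(s: SelectionResult) -> dict:
    return {
        "winners": s.winners,
        "counts": s.counts,
        "top_model": s.top_model.value,
        "k_top": s.k_top,
        "n_subjects": s.n_subjects,
        "binomial_point_p": s.binomial_point_p,
        "binomial_tail_p": s.binomial_tail_p,
    }


def t1_uncertain(cm: CellMeans) -> float:
    """T1 when target 1 was withheld from the preview."""
    return float(cm.means[0, 0])


def t1_certain(cm: CellMeans) -> float:
    """T1 averaged over conditions where target 1 was previewed."""
    return float(np.nanmean(cm.means[1:, 0]))


def mean_t2_t6(cm: CellMeans) -> float:
    """Mean of responses 2-6 over all conditions."""
    return float(np.nanmean(cm.means[:, 1:]))


def _preview_by_subject(records: Sequence[TrialRecord], n_practice: int):
    overall: dict[str, list[float]] = {}
    first_missing: dict[str, list[float]] = {}
    later_missing: dict[str, list[float]] = {}
    for r in records:
        if r.trial_index <= n_practice:
            continue
        overall.setdefault(r.subject_id, []).append(r.preview_time)
        if r.missing_target == 1:
            first_missing.setdefault(r.subject_id, []).append(r.preview_time)
        elif r.missing_target is not None:
            later_missing.setdefault(r.subject_id, []).append(r.preview_time)
    mean = lambda d: {k: float(np.mean(v)) for k, v in sorted(d.items())}
    return mean(overall), mean(first_missing), mean(later_missing)


def run_study(
    config: ExperimentConfig | str | Path,
    out_dir: str | Path | None = None,
    engine: Engine | str = Engine.EXACT,
    cutoff: float = DEFAULT_CUTOFF,
    weighted: bool = False,
    n_draws: int = DEFAULT_MC_DRAWS,
    make_plots: bool = True,
) -> dict:
    """Run the full pipeline and return the study report as a dict.

    Deterministic given the config's seed. When ``out_dir`` is given the
    trial log, per-subject cell means, fits, report JSON and summary
    figures are written there.
    """
    if isinstance(config, (str, Path)):
        config = fio.read_config(config)
    engine = Engine(engine)

    logger.info("simulating %d subjects (%s)", config.n_subjects, config.mode.value)
    records = simulate_experiment(config)

    logger.info("filtering %d trials", len(records))
    filtered, freport = filter_trials(
        records, cutoff=cutoff, n_practice=config.n_practice
    )
    per_subject = cell_means(filtered)
    curves_mean, curves_se = grand_cell_means(per_subject)

    fits = None
    selection = None
    fit_summary: dict = {}
    tests: dict[str, dict] = {}
    withheld = config.mode is Mode.WITHHELD_ONE

    if withheld:
        logger.info("fitting 4 models x %d subjects (%s)", len(per_subject), engine.value)
        fits = fit_all_models(
            per_subject,
            all_models(),
            engine=engine,
            n_draws=n_draws,
            seed=config.seed,
            weighted=weighted,
        )
        for name in all_models():
            vals = np.array([fits[sid][name].adjusted_r2 for sid in fits])
            fit_summary[name.value] = {
                "mean_adj_r2": float(np.nanmean(vals)),
                "se_adj_r2": float(np.nanstd(vals, ddof=1) / math.sqrt(len(vals))),
            }
        selection = select_model(fits)
        logger.info(
            "top model %s for %d/%d subjects",
            selection.top_model.value,
            selection.k_top,
            selection.n_subjects,
        )
        sids = sorted(per_subject)
        x_unc = [t1_uncertain(per_subject[s]) for s in sids]
        x_cer = [t1_certain(per_subject[s]) for s in sids]
        x_rest = [mean_t2_t6(per_subject[s]) for s in sids]
        tests["t1_uncertain_vs_certain"] = _test_to_dict(
            paired_t_one_tailed(x_unc, x_cer, "greater")
        )
        tests["t1_uncertain_vs_t2_t6"] = _test_to_dict(
            paired_t_one_tailed(x_unc, x_rest, "greater")
        )
        tests["t1_certain_vs_t2_t6"] = _test_to_dict(
            paired_t_one_tailed(x_cer, x_rest, "greater")
        )
    else:
        # Full-preview regime: no withheld target, so no model fitting;
        # the question is whether T1 still stands out.
        sids = sorted(per_subject)
        matrix = np.stack([per_subject[s].means[0] for s in sids])
        omnibus, pairwise = rm_anova(matrix)
        tests["response_number_anova"] = _test_to_dict(omnibus)
        tests["response_number_anova"]["df_condition"] = matrix.shape[1] - 1
        tests["pairwise_bonferroni"] = pairwise.to_dict(orient="records")
        x_t1 = matrix[:, 0]
        x_rest = matrix[:, 1:].mean(axis=1)
        tests["t1_vs_t2_t6"] = _test_to_dict(
            paired_t_one_tailed(list(x_t1), list(x_rest), "less")
        )

    overall, first_missing, later_missing = _preview_by_subject(
        records, config.n_practice
    )
    preview: dict = {
        "by_subject": overall,
        "mean": float(np.mean(list(overall.values()))),
        "sd": float(np.std(list(overall.values()), ddof=1))
        if len(overall) > 1
        else None,
    }
    if withheld and first_missing:
        sids = sorted(set(first_missing) & set(later_missing))
        preview["missing_first_mean"] = float(
            np.mean([first_missing[s] for s in sids])
        )
        preview["missing_later_mean"] = float(
            np.mean([later_missing[s] for s in sids])
        )
        tests["preview_missing_first_vs_later"] = _test_to_dict(
            paired_t_one_tailed(
                [first_missing[s] for s in sids],
                [later_missing[s] for s in sids],
                "less",
            )
        )

    report = _jsonable(
        {
            "schema_version": SCHEMA_VERSION,
            "config": config_to_dict(config),
            "filter_report": asdict(freport),
            "group_curves": {"mean": curves_mean, "se": curves_se},
            "fit_summary": fit_summary,
            "selection": _selection_to_dict(selection) if selection else None,
            "tests": tests,
            "preview": preview,
        }
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fio.trials_to_csv(records, out_dir / "trials.csv")
        cell_means_to_csv(per_subject, out_dir / "cell_means.csv")
        if fits is not None:
            fits_to_csv(fits, out_dir / "fits.csv")
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        (out_dir / "report.txt").write_text(format_report_text(report))
        if make_plots:
            _plot_curves(curves_mean, curves_se, withheld, out_dir / "mean_times.png")
            _plot_preview(preview, out_dir / "preview_times.png")
        logger.info("artifacts written to %s", out_dir)
    return report


def validate_report(report: Mapping) -> None:
    """Schema check: version and required top-level keys."""
    if report.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema {report.get('schema_version')!r}"
        )
    missing = _REQUIRED_KEYS - set(report)
    if missing:
        raise ValueError(f"report is missing keys: {sorted(missing)}")


def regenerate(report: Mapping, **kwargs) -> dict:
    """Re-run a study from a report's echoed config."""
    validate_report(report)
    return run_study(config_from_dict(report["config"]), **kwargs)


def compare_experiments(report_a: Mapping, report_b: Mapping | Sequence[Mapping]) -> dict:
    """Welch contrast of per-subject preview means between study A and
    study B (or several studies pooled as B). Overlapping subject ids are
    rejected — pooling assumes independent cohorts."""
    validate_report(report_a)
    reports_b = [report_b] if isinstance(report_b, Mapping) else list(report_b)
    for rb in reports_b:
        validate_report(rb)

    a = report_a["preview"]["by_subject"]
    b: dict[str, float] = {}
    for rb in reports_b:
        for sid, v in rb["preview"]["by_subject"].items():
            if sid in b:
                raise ValueError(f"subject id {sid!r} appears in several pooled reports")
            b[sid] = v
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"subject ids overlap between studies: {sorted(overlap)}")
    xa = np.array(list(a.values()))
    xb = np.array(list(b.values()))
    res = welch_t(xa, xb)
    return _jsonable(
        {
            "welch": _test_to_dict(res),
            "group_a": {"mean": xa.mean(), "sd": xa.std(ddof=1), "n": xa.size},
            "group_b": {"mean": xb.mean(), "sd": xb.std(ddof=1), "n": xb.size},
        }
    )


def format_report_text(report: Mapping) -> str:
    """Plain-text summary table of a study report."""
    validate_report(report)
    lines = []
    cfg = report["config"]
    lines.append(
        f"study: {cfg['n_subjects']} subjects, {cfg['n_trials']} trials, "
        f"mode {cfg['mode']}, seed {cfg['seed']}"
    )
    fr = report["filter_report"]
    lines.append(
        f"filtering: retained {fr['retention_fraction']:.2%} of post-practice "
        f"observations ({fr['n_outliers_dropped']} over cutoff); "
        f"filtered/unfiltered r = {fr['correlation_filtered_unfiltered']}"
    )
    if report["fit_summary"]:
        lines.append("mean adjusted R2 (+/- se) by model:")
        for model, s in sorted(report["fit_summary"].items()):
            lines.append(
                f"  {model:22s} {s['mean_adj_r2']:6.3f} (+/- {s['se_adj_r2']:.3f})"
            )
    sel = report["selection"]
    if sel:
        lines.append(
            f"selection: {sel['top_model']} largest adjusted R2 for "
            f"{sel['k_top']} of {sel['n_subjects']} subjects "
            f"(binomial point p = {sel['binomial_point_p']:.4e})"
        )
    for name, t in sorted(report["tests"].items()):
        if not isinstance(t, dict) or "statistic" not in t:
            continue  # pairwise tables are in the JSON/CSV exports
        if t["statistic"] is None:
            lines.append(f"{name}: undefined")
            continue
        lines.append(
            f"{name}: statistic = {t['statistic']:.2f}, df = {t['df']:.1f}, "
            f"{t['tails']}-tailed p = {t['p_value']:.4g}, "
            f"effect size = {t['effect_size']:.2f}"
        )
    pv = report["preview"]
    lines.append(f"preview time: mean {pv['mean']:.2f} s over subjects")
    if "missing_first_mean" in pv:
        lines.append(
            f"  target 1 withheld {pv['missing_first_mean']:.2f} s vs later "
            f"target withheld {pv['missing_later_mean']:.2f} s"
        )
    return "\n".join(lines) + "\n"


def _plot_curves(mean: np.ndarray, se: np.ndarray, withheld: bool, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean = np.asarray(mean, float)
    se = np.asarray(se, float)
    fig, ax = plt.subplots(figsize=(6, 4))
    responses = np.arange(1, 7)
    if withheld:
        for m in range(mean.shape[0]):
            ax.errorbar(
                responses, mean[m], yerr=se[m], marker="o", capsize=2,
                label=f"target {m + 1} withheld",
            )
        ax.legend(fontsize=7)
    else:
        ax.errorbar(responses, mean[0], yerr=se[0], marker="o", capsize=2)
    ax.set_xlabel("response number")
    ax.set_ylabel("mean time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_preview(preview: Mapping, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    if "missing_first_mean" in preview:
        labels = ["target 1\nwithheld", "target 2-6\nwithheld"]
        values = [preview["missing_first_mean"], preview["missing_later_mean"]]
    else:
        labels = ["all targets\nshown"]
        values = [preview["mean"]]
    ax.bar(labels, values)
    ax.set_ylabel("mean preview time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
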