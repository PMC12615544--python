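"""Trial exclusion and reduction to condition-by-response mean matrices.

Two exclusion rules, applied in order: the first ``n_practice`` trials of
each subject are practice and dropped whole; then any individual response
time above the cutoff (3 s by default) is excluded as an outlier while the
trial's remaining observations are kept. A whole-trial variant of the
cutoff is available behind a switch.

What remains is averaged per subject into a 6x6 (withheld condition x
response) matrix of cell means — or a 1x6 vector in the full-preview
regime — with per-cell observation counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import TrialRecord

__all__ = [
    "FilterReport",
    "CellMeans",
    "filter_trials",
    "cell_means",
    "grand_cell_means",
    "cell_means_to_csv",
    "EmptyFilterResult",
]

DEFAULT_CUTOFF = 3.0
DEFAULT_N_PRACTICE = 6


class EmptyFilterResult(ValueError):
    """Raised when filtering removes every observation."""


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one filtering pass, in units of single response-time
    observations (six per trial).

    ``retention_fraction`` is the share of post-practice observations that
    survived the cutoff. ``correlation_filtered_unfiltered`` is the Pearson
    correlation between the grand condition-by-response mean matrices with
    and without the cutoff applied (practice excluded from both).
    """

    n_total: int
    n_practice_dropped: int
    n_outliers_dropped: int
    retention_fraction: float
    correlation_filtered_unfiltered: float


@dataclass(frozen=True)
class CellMeans:
    """Per-subject mean filtered times by (condition, response) cell.

    ``means`` is 6x6 in the withheld-target design (row = withheld target
    1..6, column = response 1..6) or 1x6 under full preview; cells with no
    surviving observations are NaN with count 0.
    """

    subject_id: str
    means: np.ndarray
    counts: np.ndarray
    full_preview: bool = False

    def __post_init__(self) -> None:
        if self.means.shape != self.counts.shape:
            raise ValueError("means and counts must have the same shape")
        expected = (1, 6) if self.full_preview else (6, 6)
        if self.means.shape != expected:
            raise ValueError(f"expected {expected} matrix, got {self.means.shape}")
        self.means.setflags(write=False)
        self.counts.setflags(write=False)


def _finite(x: float) -> bool:
    return x is not None and math.isfinite(x)


def _grand_means(records: Sequence[TrialRecord]) -> np.ndarray:
    """Grand mean matrix over all subjects pooled (used only for the
    filtered-vs-unfiltered correlation)."""
    per_subject = cell_means(records)
    stacked = np.stack([cm.means for cm in per_subject.values()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        return np.nanmean(stacked, axis=0)


def filter_trials(
    records: Sequence[TrialRecord],
    cutoff: float = DEFAULT_CUTOFF,
    n_practice: int = DEFAULT_N_PRACTICE,
    whole_trial: bool = False,
) -> tuple[list[TrialRecord], FilterReport]:
    """Apply the practice-trial and long-time exclusions.

    Returns the retained records (excluded observations replaced by NaN,
    or whole trials dropped when ``whole_trial`` is set) and a
    :class:`FilterReport`. Raises :class:`EmptyFilterResult` if nothing
    survives.
    """
    if not records:
        raise ValueError("no records to filter")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    n_total = sum(1 for r in records for t in r.response_times if _finite(t))
    practice = [r for r in records if r.trial_index <= n_practice]
    main = [r for r in records if r.trial_index > n_practice]
    n_practice_dropped = sum(1 for r in practice for t in r.response_times if _finite(t))

    filtered: list[TrialRecord] = []
    n_outliers = 0
    for r in main:
        over = [(_finite(t) and t > cutoff) for t in r.response_times]
        n_over = sum(over)
        if n_over == 0:
            filtered.append(r)
            continue
        n_outliers += n_over if not whole_trial else sum(
            1 for t in r.response_times if _finite(t)
        )
        if whole_trial:
            continue
        times = tuple(
            math.nan if flag else t for t, flag in zip(r.response_times, over)
        )
        filtered.append(replace(r, response_times=times))

    n_main = n_total - n_practice_dropped
    retained = n_main - n_outliers
    if retained <= 0 or not filtered:
        raise EmptyFilterResult(
            "every observation was excluded by the practice and cutoff rules"
        )
    retention = retained / n_main if n_main else float("nan")

    corr = _filter_correlation(main, filtered)
    report = FilterReport(
        n_total=n_total,
        n_practice_dropped=n_practice_dropped,
        n_outliers_dropped=n_outliers,
        retention_fraction=retention,
        correlation_filtered_unfiltered=corr,
    )
    return filtered, report


def _filter_correlation(
    unfiltered: Sequence[TrialRecord], filtered: Sequence[TrialRecord]
) -> float:
    u = _grand_means(unfiltered).ravel()
    f = _grand_means(filtered).ravel()
    ok = np.isfinite(u) & np.isfinite(f)
    if ok.sum() < 2:
        return float("nan")
    u, f = u[ok], f[ok]
    if np.allclose(u, f):
        return 1.0  # exact identity regardless of numerical spread
    if u.std() == 0 or f.std() == 0:
        return float("nan")
    return float(np.corrcoef(u, f)[0, 1])


def cell_means(records: Sequence[TrialRecord]) -> dict[str, CellMeans]:
    """Reduce (filtered) trials to per-subject cell-mean matrices.

    NaN observations (excluded by the filter) are ignored; a cell with no
    observations is NaN with count 0 (a warning notes it). All records must
    come from a single regime: withheld-target or full-preview.
    """
    if not records:
        raise ValueError("no records given")
    modes = {r.missing_target is None for r in records}
    if len(modes) != 1:
        raise ValueError("cannot mix withheld-target and full-preview records")
    full_preview = modes.pop()

    rows = []
    for r in records:
        for j, t in enumerate(r.response_times, start=1):
            rows.append(
                (r.subject_id, 0 if full_preview else r.missing_target, j, t)
            )
    df = pd.DataFrame(rows, columns=["subject_id", "missing", "response", "time"])
    df = df[np.isfinite(df["time"])]
    if df.empty:
        raise EmptyFilterResult("no finite observations to average")

    n_rows = 1 if full_preview else 6
    out: dict[str, CellMeans] = {}
    grouped = df.groupby(["subject_id", "missing", "response"])["time"].agg(
        ["mean", "count"]
    )
    for sid in sorted({r.subject_id for r in records}):
        means = np.full((n_rows, 6), np.nan)
        counts = np.zeros((n_rows, 6), dtype=int)
        if sid in grouped.index.get_level_values(0):
            for (missing, response), row in grouped.loc[sid].iterrows():
                i = 0 if full_preview else missing - 1
                means[i, response - 1] = row["mean"]
                counts[i, response - 1] = int(row["count"])
        if (counts == 0).any():
            warnings.warn(
                f"subject {sid}: {(counts == 0).sum()} empty cell(s) left undefined",
                stacklevel=2,
            )
        out[sid] = CellMeans(
            subject_id=sid, means=means, counts=counts, full_preview=full_preview
        )
    return out


def grand_cell_means(per_subject: dict[str, CellMeans]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error over subjects of the cell-mean matrices."""
    stacked = np.stack([cm.means for cm in per_subject.values()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
        n = np.sum(np.isfinite(stacked), axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=1)
    se = sd / np.sqrt(np.maximum(n, 1))
    return mean, se


def cell_means_to_csv(per_subject: dict[str, CellMeans], path: str | Path) -> None:
    """Long-format export: subject_id, missing_target, response, mean, count."""
    rows = []
    for sid, cm in per_subject.items():
        n_rows = cm.means.shape[0]
        for i in range(n_rows):
            for j in range(6):
                rows.append(
                    {
                        "subject_id": sid,
                        "missing_target": "" if cm.full_preview else i + 1,
                        "response": j + 1,
                        "mean": cm.means[i, j],
                        "count": cm.counts[i, j],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
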