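"""Model selection across subjects and the group-level statistics.

The winning model per subject is the one with the largest adjusted R²;
the chance probability that any fixed model tops k of n subjects is
binomial with success probability 1/4 (four candidates). Group contrasts
use classical paired t tests (one-tailed where the direction is
hypothesized), a one-way repeated-measures ANOVA with Bonferroni pairwise
follow-ups, Welch's t for unequal groups, and repeated-measures Cohen's d
(d_rm, after Lakens 2013) as the effect size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .models import ModelName

__all__ = [
    "TIE",
    "Tails",
    "SelectionResult",
    "TestResult",
    "select_model",
    "binomial_point_p",
    "paired_t_one_tailed",
    "cohens_d_rm",
    "cohens_d_pooled",
    "rm_anova",
    "welch_t",
    "required_sample_size",
    "fisher_z",
]

#: marker for a subject whose best two models tie exactly on adjusted R²
TIE = "tie"

CHANCE_ONE_OF_FOUR = 0.25


class Tails(str, Enum):
    ONE = "one"
    TWO = "two"


@dataclass(frozen=True)
class TestResult:
    """A test statistic with df, p value, and an effect size."""

    statistic: float
    df: float
    p_value: float
    effect_size: float
    tails: Tails


@dataclass(frozen=True)
class SelectionResult:
    """Winner-take-all model selection over a cohort.

    ``binomial_point_p`` is the exact chance probability of the observed
    count k_top (point mass at 1/4 per subject); ``binomial_tail_p`` the
    probability of k_top or more.
    """

    winners: dict[str, str]
    counts: dict[str, int]
    top_model: ModelName
    k_top: int
    n_subjects: int
    binomial_point_p: float
    binomial_tail_p: float


def select_model(
    fits: Mapping[str, Mapping[ModelName, FitResult]],
    chance: float = CHANCE_ONE_OF_FOUR,
) -> SelectionResult:
    """Pick each subject's winner by adjusted R² and score the top model.

    Exact ties are recorded as :data:`TIE` and excluded from the top
    model's count. Every subject must have a fit for every model, all from
    one engine.
    """
    if not fits:
        raise ValueError("no fits given")
    model_names = list(ModelName)
    winners: dict[str, str] = {}
    counts: dict[str, int] = {m.value: 0 for m in model_names}
    counts[TIE] = 0
    engines = set()
    for sid, by_model in fits.items():
        missing = [m for m in model_names if m not in by_model]
        if missing:
            raise ValueError(
                f"subject {sid} lacks fits for: {[m.value for m in missing]}"
            )
        engines.update(fr.engine for fr in by_model.values())
        adj = {m: by_model[m].adjusted_r2 for m in model_names}
        best = max(adj.values())
        top = [m for m, v in adj.items() if v == best]
        if len(top) > 1:
            winners[sid] = TIE
            counts[TIE] += 1
        else:
            winners[sid] = top[0].value
            counts[top[0].value] += 1
    if len(engines) > 1:
        raise ValueError("fits mix engines; select from a single engine")
    top_name = max(model_names, key=lambda m: counts[m.value])
    k = counts[top_name.value]
    n = len(fits)
    point, tail = binomial_point_p(k, n, chance)
    counts = {m: c for m, c in counts.items() if c > 0 or m != TIE}
    return SelectionResult(
        winners=winners,
        counts=counts,
        top_model=top_name,
        k_top=k,
        n_subjects=n,
        binomial_point_p=point,
        binomial_tail_p=tail,
    )


def binomial_point_p(k: int, n: int, chance: float) -> tuple[float, float]:
    """Exact binomial point mass P(X = k) and upper tail P(X >= k)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < chance < 1:
        raise ValueError("chance must be in (0, 1)")
    point = float(stats.binom.pmf(k, n, chance))
    tail = float(stats.binom.sf(k - 1, n, chance))
    return point, tail


def paired_t_one_tailed(
    x: Sequence[float], y: Sequence[float], direction: str = "greater"
) -> TestResult:
    """Classical paired t on x - y with a one-tailed p in ``direction``
    ('greater' tests mean(x) > mean(y)). df = n - 1; effect size is d_rm."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero variance of paired differences: t undefined", stacklevel=2)
        return TestResult(math.nan, x.size - 1, math.nan, math.nan, Tails.ONE)
    res = stats.ttest_rel(x, y, alternative=direction)
    return TestResult(
        statistic=float(res.statistic),
        df=float(x.size - 1),
        p_value=float(res.pvalue),
        effect_size=cohens_d_rm(x, y),
        tails=Tails.ONE,
    )


def cohens_d_rm(x: Sequence[float], y: Sequence[float]) -> float:
    """Repeated-measures Cohen's d:
    ``(mean(x)-mean(y)) / sqrt(sx² + sy² - 2·r·sx·sy) · sqrt(2(1-r))``
    with r the paired correlation. Undefined (NaN, with warning) when a
    sample is constant or the correlation is perfect."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        warnings.warn("zero variance: d_rm undefined", stacklevel=2)
        return math.nan
    r = float(np.corrcoef(x, y)[0, 1])
    denom_sq = sx**2 + sy**2 - 2 * r * sx * sy
    if denom_sq <= 1e-15:
        warnings.warn("perfectly correlated samples: d_rm undefined", stacklevel=2)
        return math.nan
    return float((x.mean() - y.mean()) / math.sqrt(denom_sq) * math.sqrt(2 * (1 - r)))


def cohens_d_pooled(
    mean_x: float, sd_x: float, n_x: int, mean_y: float, sd_y: float, n_y: int
) -> float:
    """Between-groups Cohen's d with the pooled standard deviation."""
    pooled = math.sqrt(
        ((n_x - 1) * sd_x**2 + (n_y - 1) * sd_y**2) / (n_x + n_y - 2)
    )
    if pooled == 0:
        warnings.warn("zero pooled variance: d undefined", stacklevel=2)
        return math.nan
    return (mean_x - mean_y) / pooled


def rm_anova(matrix: np.ndarray) -> tuple[TestResult, pd.DataFrame]:
    """One-way repeated-measures ANOVA over the columns of a complete
    subjects x conditions matrix, plus all pairwise paired t tests with
    Bonferroni-multiplied p values (capped at 1).

    Returns the omnibus F with df (k-1, (k-1)(n-1)) and partial eta
    squared as the effect size. Missing cells are rejected outright.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix")
    if not np.isfinite(m).all():
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = m.shape
    grand = m.mean()
    subj_means = m.mean(axis=1)
    cond_means = m.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        warnings.warn("zero error variance: F undefined", stacklevel=2)
        f = math.nan
        p = math.nan
    else:
        f = ms_cond / ms_err
        p = float(stats.f.sf(f, df_cond, df_err))
    eta_p = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else math.nan
    omnibus = TestResult(
        statistic=float(f), df=float(df_err), p_value=p,
        effect_size=float(eta_p), tails=Tails.TWO,
    )

    n_pairs = k * (k - 1) // 2
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            res = stats.ttest_rel(m[:, a], m[:, b])
            rows.append(
                {
                    "condition_a": a + 1,
                    "condition_b": b + 1,
                    "t": float(res.statistic),
                    "df": n - 1,
                    "p_uncorrected": float(res.pvalue),
                    "p_bonferroni": min(float(res.pvalue) * n_pairs, 1.0),
                }
            )
    return omnibus, pd.DataFrame(rows)


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance t with Welch–Satterthwaite df.

    Each argument is either a 1-D sample or a ``(mean, sd, n)`` summary.
    Two-tailed p; effect size is pooled-SD Cohen's d.
    """
    mx, sx, nx = _summarize(x)
    my, sy, ny = _summarize(y)
    vx, vy = sx**2 / nx, sy**2 / ny
    if vx + vy == 0:
        warnings.warn("zero variance in both groups: t undefined", stacklevel=2)
        return TestResult(math.nan, math.nan, math.nan, math.nan, Tails.TWO)
    t = (mx - my) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    p = 2 * float(stats.t.sf(abs(t), df))
    d = cohens_d_pooled(mx, sx, nx, my, sy, ny)
    return TestResult(statistic=t, df=df, p_value=p, effect_size=d, tails=Tails.TWO)


def _summarize(v) -> tuple[float, float, int]:
    if isinstance(v, tuple) and len(v) == 3:
        mean, sd, n = v
        if n < 2:
            raise ValueError("each group needs n >= 2")
        return float(mean), float(sd), int(n)
    arr = np.asarray(v, float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("each group needs n >= 2")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def required_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: Tails | str = Tails.TWO,
    max_n: int = 100_000,
) -> int:
    """Smallest n whose one-sample t test reaches the target power.

    Power at sample size n is evaluated under the noncentral t
    distribution with df = n - 1 and noncentrality d·sqrt(n), against the
    central-t critical value at ``alpha`` (split across both tails for the
    two-tailed test). E.g. d = 0.5, alpha = .05 two-tailed, power .80
    requires n = 34.
    """
    tails = Tails(tails)
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    for n in range(2, max_n + 1):
        if _one_sample_power(n, d, alpha, tails) >= power:
            return n
    raise ValueError(f"power {power} not reachable within n <= {max_n}")


def _one_sample_power(n: int, d: float, alpha: float, tails: Tails) -> float:
    df = n - 1
    nc = d * math.sqrt(n)
    if tails is Tails.TWO:
        crit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))
    crit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(crit, df, nc))


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, arctanh(r)."""
    if not -1 < r < 1:
        raise ValueError("|r| must be < 1")
    return float(np.arctanh(r))
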