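"""The four ordinal planning models for a previewed six-click sequence.

Each trial of the task shows five of the six numbered targets in a preview;
the sixth (the *withheld* target, condition ``m`` = 1..6) appears only when
the participant ends the preview. The participant then clicks targets 1..6
in order, yielding response times T1..T6.

A planning model assigns each (condition, response) cell an ordinal
*preparation level*:

* level 1 — the response was fully prepared during the preview,
* level 2 — partly prepared; preparation finishes while the previous
  response is executed,
* level 3 — not prepared at all; specification and execution are serial.

Higher level means more residual work and hence a longer response time.
The four models differ in when the initially uncertain response is
specified (procrastination: as late as possible; pre-crastination: as
early as possible) and in whether specification can overlap execution
("fast" variants) or not ("slow" variants).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np

__all__ = [
    "ModelName",
    "ModelSpec",
    "build_model",
    "all_models",
    "predicted_times",
    "theoretical_mean_steps",
    "export_level_matrix",
]

N_CONDITIONS = 6
N_RESPONSES = 6


class ModelName(str, Enum):
    """The four candidate planning strategies."""

    SLOW_PROCRASTINATION = "slow_procrastination"
    FAST_PROCRASTINATION = "fast_procrastination"
    SLOW_PRECRASTINATION = "slow_precrastination"
    FAST_PRECRASTINATION = "fast_precrastination"


def _build_levels(name: ModelName) -> np.ndarray:
    """Construct the 6x6 level matrix (row = withheld condition m, 1-based
    internally as row index m-1; column = response j-1)."""
    L = np.ones((N_CONDITIONS, N_RESPONSES), dtype=int)
    if name is ModelName.SLOW_PROCRASTINATION:
        # Prepare only up to the uncertain target; everything from the
        # withheld target onward is specified serially during execution.
        for m in range(N_CONDITIONS):
            L[m, m:] = 3
    elif name is ModelName.FAST_PROCRASTINATION:
        # Everything except the withheld target is prepared in the preview;
        # the withheld response itself is specified serially when reached.
        for m in range(N_CONDITIONS):
            L[m, m] = 3
    elif name is ModelName.SLOW_PRECRASTINATION:
        # The withheld response is specified after the preview but before
        # the first click, lengthening T1 in every condition equally.
        L[:, 0] = 3
    elif name is ModelName.FAST_PRECRASTINATION:
        # As above when target 1 is withheld; when a later target is
        # withheld, its specification overlaps execution of response 1,
        # costing only a partial delay (level 2) on T1.
        L[0, 0] = 3
        L[1:, 0] = 2
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown model {name!r}")
    return L


@dataclass(frozen=True)
class ModelSpec:
    """A planning model: its 6x6 level matrix and free-parameter count.

    ``n_params`` is the number of distinct level values the matrix uses
    (2 for all models except Fast Pre-crastination, which uses 3).
    """

    name: ModelName
    levels: np.ndarray = field(repr=False)
    n_params: int

    def __post_init__(self) -> None:
        L = np.asarray(self.levels)
        if L.shape != (N_CONDITIONS, N_RESPONSES):
            raise ValueError("level matrix must be 6x6")
        if not np.isin(L, (1, 2, 3)).all():
            raise ValueError("level values must be in {1, 2, 3}")
        if self.n_params != len(np.unique(L)):
            raise ValueError("n_params must equal the number of distinct levels")
        self.levels.setflags(write=False)

    @property
    def used_levels(self) -> tuple[int, ...]:
        """Distinct level values present in the matrix, ascending."""
        return tuple(int(v) for v in np.unique(self.levels))


def build_model(name: ModelName | str) -> ModelSpec:
    """Return the :class:`ModelSpec` for one of the four planning models.

    Raises ``ValueError`` listing the valid names if ``name`` is unknown.
    """
    try:
        name = ModelName(name)
    except ValueError:
        valid = ", ".join(m.value for m in ModelName)
        raise ValueError(f"unknown model {name!r}; valid names: {valid}") from None
    L = _build_levels(name)
    return ModelSpec(name=name, levels=L, n_params=len(np.unique(L)))


def all_models() -> dict[ModelName, ModelSpec]:
    """All four models keyed by name."""
    return {name: build_model(name) for name in ModelName}


def predicted_times(model: ModelSpec, level_times) -> np.ndarray:
    """Map the model's level matrix to predicted times.

    ``level_times`` is the ascending triple (t1, t2, t3) of seconds for
    levels 1..3 (weak ordering t1 <= t2 <= t3 allowed). Returns the 6x6
    matrix of predicted response times.
    """
    t = np.asarray(level_times, dtype=float)
    if t.shape != (3,):
        raise ValueError("level_times must be a triple (t1, t2, t3)")
    if np.any(t < 0):
        raise ValueError("level times must be non-negative")
    if not (t[0] <= t[1] <= t[2]):
        raise ValueError("level times must be weakly ascending: t1 <= t2 <= t3")
    return t[model.levels - 1]


def theoretical_mean_steps(model: ModelSpec) -> Fraction:
    """Mean task duration in abstract time steps, one unit per level.

    Each cell of the level matrix costs its level value in steps; a row sum
    is the duration of one condition, and the result is the exact mean over
    the six conditions (e.g. 13 for Slow Procrastination, 43/6 for Fast
    Pre-crastination).
    """
    total = int(model.levels.sum())
    return Fraction(total, N_CONDITIONS)


def export_level_matrix(model: ModelSpec, path: str | Path) -> None:
    """Write the level matrix as CSV with 1-based target labels."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["missing_target"] + [f"response_{j}" for j in range(1, 7)])
        for m in range(N_CONDITIONS):
            writer.writerow([m + 1] + [int(v) for v in model.levels[m]])
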