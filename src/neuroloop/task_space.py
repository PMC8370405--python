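"""Two-dimensional task x difficulty search space.

The closed loop searches a discrete grid with one axis enumerating cognitive
tasks (ordered so that tasks expected to elicit similar network responses are
neighbours) and one axis enumerating difficulty levels of increasing demand.
Conditions live on an integer lattice; grid coordinates are fed raw to the
Gaussian-process kernel and anisotropy between the two axes is absorbed by
per-dimension lengthscales, which keeps lengthscales interpretable in grid
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default task ordering along the task axis (a configuration input; the
#: ordering encodes prior similarity between tasks).
DEFAULT_TASK_NAMES: tuple[str, ...] = (
    "Overt Naming",
    "Auditory Comprehension",
    "Semantic Judgement",
    "Verbal Learning",
    "Calculation",
    "Go/No-Go",
    "Encoding",
)

DEFAULT_N_DIFFICULTY = 3


@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the grid: 1-based task position and difficulty level."""

    task_index: int
    difficulty: int


@dataclass(frozen=True)
class TaskSpace:
    """Ordered T x D grid of experimental conditions.

    Coordinates are the raw lattice integers ``(task_index, difficulty)``
    cast to floats; the mapping condition -> coordinate is injective by
    construction.
    """

    task_names: tuple[str, ...]
    n_difficulty: int
    _conditions: tuple[Condition, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        conds = tuple(
            Condition(t, d)
            for t in range(1, self.n_tasks + 1)
            for d in range(1, self.n_difficulty + 1)
        )
        object.__setattr__(self, "_conditions", conds)

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    @property
    def n_conditions(self) -> int:
        return self.n_tasks * self.n_difficulty

    def conditions(self) -> tuple[Condition, ...]:
        """All conditions in deterministic row-major order (task outer)."""
        return self._conditions

    def contains(self, condition: Condition) -> bool:
        return (
            1 <= condition.task_index <= self.n_tasks
            and 1 <= condition.difficulty <= self.n_difficulty
        )

    def validate(self, condition: Condition) -> None:
        if not self.contains(condition):
            raise ValueError(
                f"condition {condition} outside {self.n_tasks}x{self.n_difficulty} grid"
            )

    def coordinates(self, condition: Condition) -> tuple[float, float]:
        """Kernel coordinates of a condition (raw lattice position)."""
        self.validate(condition)
        return (float(condition.task_index), float(condition.difficulty))

    def coordinate_array(self) -> np.ndarray:
        """(n_conditions, 2) array of coordinates in enumeration order."""
        return np.array([self.coordinates(c) for c in self._conditions])

    def index_of(self, condition: Condition) -> int:
        """Position of a condition in the row-major enumeration."""
        self.validate(condition)
        return (condition.task_index - 1) * self.n_difficulty + (condition.difficulty - 1)

    def condition_at(self, index: int) -> Condition:
        return self._conditions[index]

    def nearest_condition(self, xy: tuple[float, float]) -> Condition:
        """Grid point closest (Euclidean) to an arbitrary coordinate pair."""
        coords = self.coordinate_array()
        i = int(np.argmin(((coords - np.asarray(xy, dtype=float)) ** 2).sum(axis=1)))
        return self._conditions[i]

    def task_name(self, condition: Condition) -> str:
        self.validate(condition)
        return self.task_names[condition.task_index - 1]

    def condition_label(self, condition: Condition) -> str:
        return f"{self.task_name(condition)} (level {condition.difficulty})"


def build_task_space(
    task_names: tuple[str, ...] | list[str] = DEFAULT_TASK_NAMES,
    n_difficulty: int = DEFAULT_N_DIFFICULTY,
) -> TaskSpace:
    """Build the T x D grid of conditions.

    Parameters
    ----------
    task_names:
        Ordered task labels along the task axis (>= 1 task, unique).
    n_difficulty:
        Number of difficulty levels per task (>= 1).
    """
    names = tuple(task_names)
    if len(names) == 0:
        raise ValueError("task_names must contain at least one task")
    if len(set(names)) != len(names):
        raise ValueError("task_names must be unique")
    if n_difficulty < 1:
        raise ValueError("n_difficulty must be >= 1")
    return TaskSpace(task_names=names, n_difficulty=int(n_difficulty))


def enumerate_conditions(space: TaskSpace) -> list[Condition]:
    """Deterministic row-major condition ordering (task outer, difficulty inner)."""
    return list(space.conditions())
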