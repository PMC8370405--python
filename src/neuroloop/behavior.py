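"""Chance-level permutation distributions and AUROC for in-scanner accuracy.

For each task condition the empirical distribution is the per-subject mean
block accuracy; the chance distribution is built by shuffling, within each
block independently, the response sequence against the answer sequence and
recomputing accuracies — preserving each subject's overall response pattern.
AUROC between the two distributions (ties half-weighted) measures how far
performance lies above chance; significance requires the one-sided lower 95%
bootstrap confidence bound to exceed 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import TrialRecord
from .task_space import Condition, TaskSpace

__all__ = [
    "auroc",
    "ChanceDistribution",
    "AurocResult",
    "chance_distribution",
    "auroc_vs_chance",
    "behaviour_table",
    "DEFAULT_EXCLUDED_CONDITIONS",
]

#: Conditions with no computable chance-level accuracy: Overt Naming requires
#: no keypad response at any level; the easiest Auditory Comprehension level
#: is always answered correctly.
DEFAULT_EXCLUDED_CONDITIONS: tuple = (
    ("Overt Naming", 1),
    ("Overt Naming", 2),
    ("Overt Naming", 3),
    ("Auditory Comprehension", 1),
)


def auroc(sample_a, sample_b) -> float:
    """P(a > b) + 0.5 P(a = b) over all pairs (rank-sum formulation).

    0.5 means no separation between the two distributions; 1.0 means every
    value of ``sample_a`` exceeds every value of ``sample_b``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    # Mann-Whitney U for sample a, from its rank sum
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2
    return float(u / (a.size * b.size))


@dataclass(frozen=True)
class ChanceDistribution:
    """Pooled permuted per-subject mean accuracies for one condition."""

    condition: Condition
    values: np.ndarray
    n_permutations: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("permuted accuracies must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AurocResult:
    condition: Condition
    auroc: float
    lower_bound_95: float
    significant: bool


def _permuted_block_accuracies(block: TrialRecord, n_permutations: int, rng) -> np.ndarray:
    """Accuracy of each within-block response permutation vs fixed answers."""
    answers = np.asarray(block.answers, dtype=object)
    responses = np.asarray(block.responses, dtype=object)
    n = answers.size
    if n < 2:
        return np.full(n_permutations, float(np.mean(block.correct)))
    perm_idx = rng.permuted(
        np.tile(np.arange(n), (n_permutations, 1)), axis=1
    )
    permuted = responses[perm_idx]  # (n_permutations, n)
    return (permuted == answers[None, :]).mean(axis=1)


def chance_distribution(
    trials, n_permutations: int = 1000, rng_seed=None
) -> ChanceDistribution:
    """Chance accuracy distribution for one condition's blocks.

    Per permutation and subject: permute each block's responses against its
    answers, recompute the block accuracies and average them over the
    subject's blocks of this condition; all subjects' permuted means are
    pooled into one vector (n_permutations x n_subjects values).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("chance_distribution requires at least one block")
    condition = trials[0].condition
    if any(t.condition != condition for t in trials):
        raise ValueError("all blocks must share one condition")
    rng = np.random.default_rng(rng_seed)

    by_subject: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)

    pooled = []
    for blocks in by_subject.values():
        per_block = np.stack(
            [_permuted_block_accuracies(b, n_permutations, rng) for b in blocks]
        )
        pooled.append(per_block.mean(axis=0))  # subject mean per permutation
    return ChanceDistribution(
        condition=condition,
        values=np.concatenate(pooled),
        n_permutations=n_permutations,
    )


def auroc_vs_chance(
    empirical_accuracies,
    chance: ChanceDistribution,
    n_bootstrap: int = 10_000,
    rng_seed=None,
) -> AurocResult:
    """AUROC of empirical subject accuracies against the chance distribution.

    The bootstrap resamples subjects (the atoms of the empirical distribution)
    with replacement, recomputing AUROC against the fixed chance vector; the
    lower 95% bound is the 5th percentile, and significance requires that
    bound to exceed 0.5.
    """
    emp = np.asarray(empirical_accuracies, dtype=float)
    if emp.size < 2:
        raise ValueError("need >= 2 subjects for a bootstrap confidence bound")
    rng = np.random.default_rng(rng_seed)
    point = auroc(emp, chance.values)

    # rank the fixed chance sample once; AUROC of a resample is then a mean of
    # per-subject exceedance probabilities, which resampling averages over
    exceed = np.array([auroc([e], chance.values) for e in np.atleast_1d(emp)])
    idx = rng.integers(0, emp.size, size=(n_bootstrap, emp.size))
    boot = exceed[idx].mean(axis=1)
    lower = float(np.percentile(boot, 5))
    return AurocResult(
        condition=chance.condition,
        auroc=point,
        lower_bound_95=lower,
        significant=lower > 0.5,
    )


def behaviour_table(
    trials,
    space: TaskSpace,
    group: str = "patient",
    groups: dict | None = None,
    n_permutations: int = 1000,
    n_bootstrap: int = 10_000,
    rng_seed=None,
    excluded_conditions=DEFAULT_EXCLUDED_CONDITIONS,
) -> pd.DataFrame:
    """Per-condition AUROC-vs-chance results for one group.

    ``groups`` maps subject_id -> group label; blocks of other groups are
    ignored. Conditions in ``excluded_conditions`` (task name, difficulty)
    or with fewer than two subjects are reported as missing (NaN) rather than
    silently dropped.
    """
    groups = groups or {}
    root = np.random.SeedSequence(rng_seed)
    rows = []
    excluded = set(excluded_conditions)
    for cond in space.conditions():
        label = space.task_name(cond)
        cond_trials = [
            t
            for t in trials
            if t.condition == cond and groups.get(t.subject_id, group) == group
        ]
        by_subj: dict[str, list[float]] = {}
        for t in cond_trials:
            by_subj.setdefault(t.subject_id, []).append(t.accuracy)
        emp = np.array([float(np.mean(v)) for v in by_subj.values()])
        missing = (label, cond.difficulty) in excluded or emp.size < 2
        if missing:
            rows.append(
                dict(
                    task=label,
                    difficulty=cond.difficulty,
                    n_subjects=emp.size,
                    auroc=np.nan,
                    lower_bound_95=np.nan,
                    significant=False,
                    missing=True,
                )
            )
            continue
        s1, s2 = root.spawn(2)
        chance = chance_distribution(cond_trials, n_permutations, s1)
        res = auroc_vs_chance(emp, chance, n_bootstrap, s2)
        rows.append(
            dict(
                task=label,
                difficulty=cond.difficulty,
                n_subjects=emp.size,
                auroc=res.auroc,
                lower_bound_95=res.lower_bound_95,
                significant=res.significant,
                missing=False,
            )
        )
    return pd.DataFrame(rows)
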