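"""Intra-subject reliability of functional profiles across two runs.

The observed statistic per subject is the Spearman correlation between the
GP posterior-mean profiles of run 1 and run 2. The null is built by
permuting, within each subject, the run-2 contrast values against their
sampled conditions (the condition multiset is preserved), refitting the GP
with the same fixed hyperparameters, and recomputing the correlation. Group
evidence is the median Fisher-z transformed correlation per group; per
permutation only the maximum of the two group medians is kept (max-statistic
method), giving family-wise control across groups with a one-sided test.

Because the permutation leaves the sampled conditions fixed, the GP mean is
an affine function of the permuted values with a constant linear operator,
so all permutations are computed with one matrix product per subject; this
is algebraically identical to refitting the GP per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from scipy.stats import spearmanr as _spearmanr

from .gp import GPConfig, posterior_mean_operator
from .loop import predict_profile
from .task_space import TaskSpace

__all__ = ["spearman", "fisher_z", "ReliabilityResult", "reliability_test"]

_RHO_CLIP = 1 - 1e-6


def spearman(profile_a, profile_b) -> float:
    """Spearman rank correlation (ties averaged); NaN for a constant input."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("profiles must share a length of >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(_spearmanr(a, b).statistic)


def fisher_z(rho) -> np.ndarray:
    """arctanh with |rho| clipped just inside 1 so group medians stay finite."""
    return np.arctanh(np.clip(rho, -_RHO_CLIP, _RHO_CLIP))


@dataclass(frozen=True)
class ReliabilityResult:
    per_subject_rho: dict
    group_median_z: dict
    p_value: dict
    n_permutations: int
    # permutation diagnostics: per-group null medians and their running max
    null_group_medians: dict | None = None
    null_max: np.ndarray | None = None


def _rank_columns(x: np.ndarray) -> np.ndarray:
    return rankdata(x, axis=0)


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of b's columns with the vector a."""
    a = a - a.mean()
    b = b - b.mean(axis=0, keepdims=True)
    denom = np.sqrt((a**2).sum() * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a @ b) / denom


def reliability_test(
    run1_obs: dict,
    run2_obs: dict,
    group_labels: dict,
    space: TaskSpace,
    gp_config: GPConfig,
    n_permutations: int = 10_000,
    rng_seed=None,
) -> ReliabilityResult:
    """Permutation test of between-run profile reliability per group.

    Parameters
    ----------
    run1_obs, run2_obs:
        Mapping subject_id -> list of observations (or (condition, value)
        pairs) for each run; every subject must appear in both.
    group_labels:
        Mapping subject_id -> group label (e.g. "control"/"patient").
    """
    subjects = list(run1_obs)
    if set(subjects) != set(run2_obs):
        raise ValueError("every subject needs observations for both runs")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(rng_seed)
    groups = sorted(set(group_labels[s] for s in subjects))

    observed_rho: dict[str, float] = {}
    null_rho = np.empty((len(subjects), n_permutations))
    for si, subj in enumerate(subjects):
        profile1 = predict_profile(run1_obs[subj], space, gp_config)
        profile2 = predict_profile(run2_obs[subj], space, gp_config)
        observed_rho[subj] = spearman(profile1, profile2)

        conds, values = [], []
        for obs in run2_obs[subj]:
            cond, val = (obs.condition, obs.value) if hasattr(obs, "condition") else obs
            conds.append(cond)
            values.append(float(val))
        y = np.asarray(values)
        b_op, w = posterior_mean_operator(conds, space, gp_config)
        perm_idx = rng.permuted(np.tile(np.arange(y.size), (n_permutations, 1)), axis=1)
        y_perm = y[perm_idx].T  # (n_obs, n_perm)
        if gp_config.standardize_y:
            means = y.mean()  # permutation-invariant
            profiles = means * (1 - w)[:, None] + b_op @ y_perm
        else:
            profiles = b_op @ y_perm
        ranks1 = rankdata(profile1)
        null_rho[si] = _pearson_columns(ranks1, _rank_columns(profiles))

    observed_z = fisher_z(np.array([observed_rho[s] for s in subjects]))
    null_z = fisher_z(null_rho)
    group_masks = {g: np.array([group_labels[s] == g for s in subjects]) for g in groups}

    group_median_z = {
        g: float(np.median(observed_z[m])) for g, m in group_masks.items()
    }
    null_medians = np.stack(
        [np.median(null_z[m], axis=0) for m in group_masks.values()]
    )  # (n_groups, n_perm)
    null_max = null_medians.max(axis=0)
    p_value = {
        g: float((1 + np.sum(null_max >= group_median_z[g])) / (1 + n_permutations))
        for g in groups
    }
    return ReliabilityResult(
        per_subject_rho=observed_rho,
        group_median_z=group_median_z,
        p_value=p_value,
        n_permutations=n_permutations,
        null_group_medians={g: null_medians[i] for i, g in enumerate(group_masks)},
        null_max=null_max,
    )
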