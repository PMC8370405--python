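"""Incremental block-design GLM on network-averaged BOLD time courses.

After each completed task block the design is rebuilt with one HRF-convolved
boxcar regressor per block observed so far (plus intercept and linear drift),
refit by ordinary least squares on each network's time course, and the
FPN>DMN contrast for the just-completed block is the difference of the two
networks' beta estimates for that block's regressor.

Estimation is plain OLS without prewhitening: the real-time setting leaves no
room for iterative noise modelling, so serial correlation is part of the
simulator's challenge rather than the estimator's job. The first fit happens
only once the burn-in blocks are all acquired; the earlier blocks' contrasts
are back-filled from that first fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank deficient."""


def double_gamma_hrf(tr_seconds: float, duration_seconds: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at TR spacing.

    Positive gamma peaking at 6 s minus an undershoot peaking at 16 s with
    1/6 relative amplitude; peak normalized to 1 so regressor amplitude maps
    directly onto boxcar amplitude.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    t = np.arange(0, duration_seconds + tr_seconds / 2, tr_seconds)
    peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


@dataclass(frozen=True)
class DesignMatrix:
    """Design with one task regressor per block, then intercept and drift."""

    matrix: np.ndarray
    n_task_regressors: int
    tr_seconds: float

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class GlmResult:
    """Per-block network betas and the contrast of interest."""

    beta_fpn: np.ndarray
    beta_dmn: np.ndarray

    @property
    def contrasts(self) -> np.ndarray:
        """beta_FPN - beta_DMN for every task regressor."""
        return self.beta_fpn - self.beta_dmn


def build_design(
    onsets_seconds,
    durations_seconds,
    n_scans: int,
    tr_seconds: float,
) -> DesignMatrix:
    """HRF-convolved boxcar design for the task blocks observed so far.

    One column per block (in onset order), followed by an intercept and a
    centred linear drift term. Instruction and pre-task rest periods are
    unmodelled baseline. Blocks must not overlap.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if n_scans < 2:
        raise ValueError("n_scans must be >= 2")
    onsets = np.asarray(onsets_seconds, dtype=float)
    durations = np.asarray(durations_seconds, dtype=float)
    if onsets.shape != durations.shape:
        raise ValueError("onsets and durations must have the same length")
    if np.any(onsets < 0) or np.any(durations <= 0):
        raise ValueError("onsets must be >= 0 and durations > 0")
    total = n_scans * tr_seconds
    if np.any(onsets + durations > total + 1e-9):
        raise ValueError("block extends past the scanned interval")
    order = np.argsort(onsets)
    ends = onsets[order] + durations[order]
    if np.any(onsets[order][1:] < ends[:-1] - 1e-9):
        raise ValueError("task blocks overlap")

    scan_times = np.arange(n_scans) * tr_seconds
    hrf = double_gamma_hrf(tr_seconds)
    cols = []
    for onset, dur in zip(onsets, durations):
        boxcar = ((scan_times >= onset - 1e-9) & (scan_times < onset + dur - 1e-9)).astype(float)
        cols.append(np.convolve(boxcar, hrf)[:n_scans])
    intercept = np.ones(n_scans)
    drift = scan_times - scan_times.mean()
    if drift.std() > 0:
        drift = drift / drift.std()
    matrix = np.column_stack(cols + [intercept, drift])
    return DesignMatrix(matrix=matrix, n_task_regressors=len(cols), tr_seconds=tr_seconds)


def fit_glm(timecourse: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Ordinary least-squares betas for one network time course."""
    y = np.asarray(timecourse, dtype=float)
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError(f"time course length {y.shape[0]} != design rows {x.shape[0]}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return beta


def fit_networks(fpn_tc, dmn_tc, design: DesignMatrix) -> GlmResult:
    """Fit both networks on the shared design; betas of the task regressors."""
    k = design.n_task_regressors
    return GlmResult(
        beta_fpn=fit_glm(fpn_tc, design)[:k],
        beta_dmn=fit_glm(dmn_tc, design)[:k],
    )


def block_contrast(fpn_tc, dmn_tc, design: DesignMatrix, block_index: int) -> float:
    """FPN>DMN contrast for one block: beta_FPN[i] - beta_DMN[i]."""
    if not 0 <= block_index < design.n_task_regressors:
        raise IndexError(
            f"block_index {block_index} out of range (0..{design.n_task_regressors - 1})"
        )
    return float(fit_networks(fpn_tc, dmn_tc, design).contrasts[block_index])
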