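"""Closed-loop task selection: random burn-in, then GP-UCB.

Each run consists of a fixed number of iterations. The first ``n_burn_in``
conditions are drawn uniformly at random (with replacement) across the grid;
from then on the GP is refit on every observation collected so far and the
next condition is the GP-UCB argmax. The subject is abstracted as an oracle
callback mapping a condition to one observed contrast value, so the same loop
drives the fast direct-noise simulator, the full BOLD-plus-GLM path, or (in
principle) a real acquisition system.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import glm as glm_mod
from .cohort import BlockTiming, CohortParams, GroundTruthSubject, simulate_block
from .gp import GPConfig, GPPosterior, Observation, gp_fit, ucb_select
from .task_space import Condition, TaskSpace

__all__ = [
    "RunRecord",
    "run_closed_loop",
    "predict_profile",
    "DirectOracle",
    "IncrementalGlmOracle",
]

DEFAULT_N_ITERATIONS = 16
DEFAULT_N_BURN_IN = 4


@dataclass(frozen=True)
class RunRecord:
    """One optimization run: ordered observations and the final posterior."""

    subject_id: str
    run: int
    observations: tuple
    final_posterior: GPPosterior
    rng_seed: int | None


def run_closed_loop(
    subject_oracle,
    space: TaskSpace,
    config: GPConfig,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    n_burn_in: int = DEFAULT_N_BURN_IN,
    rng_seed=None,
    subject_id: str = "subject",
    run: int = 1,
) -> RunRecord:
    """Execute one closed-loop optimization run.

    ``subject_oracle`` is called once per iteration with the selected
    Condition and must return a finite contrast value. If the oracle exposes
    a ``block_contrasts()`` method (the incremental-GLM path), the burn-in
    observations are back-filled from the estimates available after the last
    burn-in block — matching a system whose first GLM fit happens only once
    the burn-in is complete.
    """
    if n_burn_in > n_iterations:
        raise ValueError("n_burn_in cannot exceed n_iterations")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(rng_seed)
    conditions = space.conditions()
    observations: list[Observation] = []

    for it in range(1, n_iterations + 1):
        if it <= n_burn_in:
            cond = conditions[int(rng.integers(space.n_conditions))]
        else:
            posterior = gp_fit(observations, space, config)
            cond = ucb_select(posterior, space, config, rng)
        try:
            value = float(subject_oracle(cond))
        except Exception as exc:  # annotate with loop context
            raise RuntimeError(
                f"oracle failed at iteration {it} ({space.condition_label(cond)})"
            ) from exc
        observations.append(
            Observation(
                subject_id=subject_id,
                run=run,
                iteration=it,
                condition=cond,
                value=value,
                burn_in=it <= n_burn_in,
            )
        )
        if it == n_burn_in and hasattr(subject_oracle, "block_contrasts"):
            contrasts = np.asarray(subject_oracle.block_contrasts(), dtype=float)
            observations = [
                replace(obs, value=float(contrasts[i]))
                for i, obs in enumerate(observations)
            ]

    final = gp_fit(observations, space, config)
    return RunRecord(
        subject_id=subject_id,
        run=run,
        observations=tuple(observations),
        final_posterior=final,
        rng_seed=rng_seed if isinstance(rng_seed, (int, np.integer)) else None,
    )


def predict_profile(observations, space: TaskSpace, config: GPConfig) -> np.ndarray:
    """Posterior-mean functional profile over all conditions.

    Pools the given observations (one run, or both runs collapsed) into a
    single GP fit and returns the 21 posterior means in enumeration order.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("predict_profile requires at least one observation")
    return gp_fit(observations, space, config).mean


class DirectOracle:
    """Fast subject oracle: ground-truth value plus Gaussian contrast noise."""

    def __init__(
        self,
        subject: GroundTruthSubject,
        space: TaskSpace,
        rng,
        params: CohortParams | None = None,
    ) -> None:
        self.subject = subject
        self.space = space
        self.params = params or CohortParams()
        self.rng = np.random.default_rng(rng)

    def __call__(self, condition: Condition) -> float:
        return simulate_block(
            self.subject, condition, "direct", self.rng, self.space, self.params
        )


class IncrementalGlmOracle:
    """Full-fidelity oracle: simulate BOLD blocks, refit the GLM incrementally.

    Maintains the run's concatenated FPN/DMN time courses (including initial
    equilibration scans, left as unmodelled baseline) and, after each block,
    rebuilds the design with one regressor per completed block and returns
    the just-completed block's beta contrast. ``block_contrasts()`` exposes
    all per-block contrasts from the current fit, which the loop uses to
    back-fill burn-in observations.
    """

    def __init__(
        self,
        subject: GroundTruthSubject,
        space: TaskSpace,
        rng,
        params: CohortParams | None = None,
        timing: BlockTiming | None = None,
        equilibration_trs: int = 10,
    ) -> None:
        self.subject = subject
        self.space = space
        self.params = params or CohortParams()
        self.timing = timing or BlockTiming()
        self.rng = np.random.default_rng(rng)
        bold = self.params.bold
        self._tr = bold.tr_seconds
        self._n_eq = int(equilibration_trs)
        from .cohort import ar1_noise

        # noise accrues per acquired segment; task signal is rebuilt at run
        # level each fit so HRF tails spill correctly across block boundaries
        self._noise_fpn = [ar1_noise(self._n_eq, bold.noise_sd, bold.ar1_coefficient, self.rng)]
        self._noise_dmn = [ar1_noise(self._n_eq, bold.noise_sd, bold.ar1_coefficient, self.rng)]
        self._onsets: list[float] = []
        self._amps: list[tuple[float, float]] = []

    @property
    def _n_scans(self) -> int:
        return self._n_eq + len(self._onsets) * int(round(self.timing.total_s / self._tr))

    def _signals(self) -> tuple[np.ndarray, np.ndarray]:
        from .cohort import _task_regressor

        bold = self.params.bold
        n = self._n_scans
        t = np.arange(n) * self._tr
        drift = bold.drift_per_second * (t - t.mean())
        fpn = drift + np.concatenate(self._noise_fpn)
        dmn = drift + np.concatenate(self._noise_dmn)
        for onset, (a_f, a_d) in zip(self._onsets, self._amps):
            reg = _task_regressor(n, onset, self.timing.task_s, self._tr)
            fpn = fpn + a_f * reg
            dmn = dmn + a_d * reg
        return fpn, dmn

    def __call__(self, condition: Condition) -> float:
        from .cohort import ar1_noise

        self.space.validate(condition)
        bold = self.params.bold
        f = self.subject.true_value(self.space, condition)
        block_start = self._n_scans * self._tr
        self._onsets.append(block_start + self.timing.task_onset_s)
        self._amps.append((bold.fpn_baseline + 0.5 * f, bold.dmn_baseline - 0.5 * f))
        n_block = int(round(self.timing.total_s / self._tr))
        self._noise_fpn.append(
            ar1_noise(n_block, bold.noise_sd, bold.ar1_coefficient, self.rng)
        )
        self._noise_dmn.append(
            ar1_noise(n_block, bold.noise_sd, bold.ar1_coefficient, self.rng)
        )
        return float(self.block_contrasts()[-1])

    def block_contrasts(self) -> np.ndarray:
        """beta_FPN - beta_DMN for every completed block, from the current fit."""
        fpn, dmn = self._signals()
        design = glm_mod.build_design(
            self._onsets,
            [self.timing.task_s] * len(self._onsets),
            n_scans=len(fpn),
            tr_seconds=self._tr,
        )
        return glm_mod.fit_networks(fpn, dmn, design).contrasts
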