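"""Synthetic cohort generator: ground-truth contrast surfaces, block-wise
network BOLD time courses, and trial-level behaviour.

The generator stands in for the scanner and the participants. Controls share
a canonical FPN>DMN contrast surface — a smooth ridge peaking over the tasks
that maximally dissociate the frontoparietal from the default-mode network,
increasing with difficulty — plus a small smooth individual perturbation.
Patients attenuate the canonical surface in proportion to a severity parameter
and add an idiosyncratic smooth distortion whose amplitude also scales with
severity, so that higher severity yields both weaker dissociation and more
individually heterogeneous profiles. Behaviour (per-trial accuracy and
reaction time) degrades with group, severity and difficulty, linking the
functional distortion to performance the downstream analyses are meant to
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gp import GPConfig, kernel_matrix
from .task_space import Condition, TaskSpace

__all__ = [
    "BlockTiming",
    "BoldParams",
    "BehaviourParams",
    "CohortParams",
    "GroundTruthSubject",
    "BlockTimecourses",
    "TrialRecord",
    "Cohort",
    "canonical_surface",
    "smooth_perturbation",
    "sample_control_surface",
    "sample_patient_surface",
    "simulate_block",
    "simulate_trials",
    "generate_cohort",
]

NO_RESPONSE = "no response"


@dataclass(frozen=True)
class BlockTiming:
    """Timing of one loop iteration, in seconds.

    Defaults: 5 s instruction, 3 s pre-task rest, 34 s task, 10 s rest,
    i.e. a 52 s iteration.
    """

    instruction_s: float = 5.0
    pre_rest_s: float = 3.0
    task_s: float = 34.0
    post_rest_s: float = 10.0

    @property
    def total_s(self) -> float:
        return self.instruction_s + self.pre_rest_s + self.task_s + self.post_rest_s

    @property
    def task_onset_s(self) -> float:
        """Task onset relative to iteration start."""
        return self.instruction_s + self.pre_rest_s


@dataclass(frozen=True)
class BoldParams:
    """Forward BOLD model for one block's network time courses.

    Each network's signal is amplitude x (task boxcar convolved with the
    canonical double-gamma HRF) plus a linear drift and AR(1) Gaussian noise,
    sampled at TR. The FPN amplitude is ``fpn_baseline + f*/2`` and the DMN
    amplitude ``dmn_baseline - f*/2`` so the amplitude difference equals the
    ground-truth contrast.
    """

    tr_seconds: float = 2.0
    fpn_baseline: float = 0.5
    dmn_baseline: float = 0.5
    drift_per_second: float = 0.005
    ar1_coefficient: float = 0.3
    noise_sd: float = 1.0


@dataclass(frozen=True)
class BehaviourParams:
    """Logistic accuracy and log-normal RT model for in-scanner trials.

    Accuracy follows a psychometric curve with a forced-choice guessing
    floor at 1/K for a task with K response categories:

        p_correct = 1/K + (1 - 1/K) * sigmoid(eta)
        eta = intercept + group_effect*[patient] + severity_slope*severity
              + difficulty_slope*(difficulty-1) + task_offset + subject_intercept

    so even a fully impaired subject guesses at chance rather than below it.
    Verbal Learning's task offset drives eta far negative, pinning both
    groups at chance (an ill-designed task); Overt Naming requires no keypad
    press so its trials carry no responses (coded incorrect); the easiest
    Auditory Comprehension level is always answered correctly, so no chance
    level can be computed for it downstream.
    """

    intercept: float = 2.2
    group_effect: float = -0.8
    severity_slope: float = -1.5
    difficulty_slope: float = -0.5
    subject_intercept_sd: float = 0.3
    n_categories_default: int = 4
    n_categories_by_task: dict = field(default_factory=lambda: {"Go/No-Go": 2})
    task_offsets: dict = field(default_factory=lambda: {"Verbal Learning": -8.0})
    no_response_tasks: tuple = ("Overt Naming",)
    always_correct: tuple = ((("Auditory Comprehension"), 1),)
    n_trials_per_block: int = 8
    rt_log_mean: float = float(np.log(800.0))
    rt_group_shift: float = 0.25
    rt_severity_shift: float = 0.3
    rt_difficulty_shift: float = 0.1
    rt_log_sd: float = 0.3
    response_window_ms: float = 3500.0


@dataclass(frozen=True)
class CohortParams:
    """All generator knobs with the study's default conditions.

    The canonical surface is a ridge over the optimal tasks (amplitude
    ``ridge_amplitude``, width ``ridge_width`` in grid units) on top of a
    negative baseline, plus ``difficulty_slope`` per difficulty level. The
    ridge width matches the GP task lengthscale: the task axis is ordered so
    that similar tasks are adjacent, which is exactly the smoothness the
    model assumes.

    ``obs_noise_sd`` is the per-block contrast noise for controls; patient
    noise is scaled by ``1 + noise_severity_slope * severity``. Both were
    calibrated once so that the simulated between-run profile reliability
    reproduces the reported group medians (about 0.9 for controls, about 0.7
    for patients); the per-block noise level itself is not an empirically
    reported quantity.
    """

    optimal_tasks: tuple = ("Semantic Judgement", "Calculation", "Encoding")
    baseline: float = -0.2
    ridge_amplitude: float = 0.8
    ridge_width: float = 1.5
    difficulty_slope: float = 0.3
    control_perturbation_sd: float = 0.1
    patient_attenuation: float = 0.5
    patient_perturbation_sd: float = 0.6
    perturbation_lengthscale_task: float = 1.5
    perturbation_lengthscale_difficulty: float = 1.0
    obs_noise_sd: float = 0.08
    noise_severity_slope: float = 5.0
    severity_range: tuple = (0.2, 1.0)
    lesion_log_mean: float = float(np.log(7.0))
    lesion_log_sd: float = 0.8
    lesion_severity_correlation: float = 0.5
    bold: BoldParams = field(default_factory=BoldParams)
    behaviour: BehaviourParams = field(default_factory=BehaviourParams)


@dataclass(frozen=True)
class GroundTruthSubject:
    """One synthetic participant with a known contrast surface."""

    subject_id: str
    group: str  # "control" | "patient"
    true_surface: np.ndarray  # f*(c) per condition, enumeration order
    severity: float
    obs_noise_sd: float
    lesion_volume: float
    subject_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "control" and self.severity != 0:
            raise ValueError("controls must have severity 0")
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must lie in [0, 1]")
        if self.obs_noise_sd <= 0:
            raise ValueError("obs_noise_sd must be positive")
        surf = np.asarray(self.true_surface, dtype=float)
        if not np.all(np.isfinite(surf)):
            raise ValueError("true surface must be finite everywhere")
        object.__setattr__(self, "true_surface", surf)

    def true_value(self, space: TaskSpace, condition: Condition) -> float:
        return float(self.true_surface[space.index_of(condition)])


@dataclass(frozen=True)
class BlockTimecourses:
    """Network-averaged BOLD samples for one block, at TR spacing."""

    fpn: np.ndarray
    dmn: np.ndarray
    tr_seconds: float
    task_onset_s: float
    task_duration_s: float

    def __post_init__(self) -> None:
        if len(self.fpn) != len(self.dmn):
            raise ValueError("fpn and dmn time courses must have equal length")


@dataclass(frozen=True)
class TrialRecord:
    """Trial-level behaviour for one task block."""

    subject_id: str
    run: int
    block_index: int
    condition: Condition
    answers: tuple
    responses: tuple
    correct: tuple
    rt_ms: tuple  # NaN where no response was given

    def __post_init__(self) -> None:
        n = len(self.answers)
        if not (len(self.responses) == len(self.correct) == len(self.rt_ms) == n):
            raise ValueError("per-trial fields must have equal length")
        for r, a, c in zip(self.responses, self.answers, self.correct):
            if c != (r == a):
                raise ValueError("correct flags inconsistent with answers/responses")

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.correct))


@dataclass(frozen=True)
class Cohort:
    subjects: tuple
    n_runs: int
    params: CohortParams
    master_seed: int

    @property
    def controls(self) -> list:
        return [s for s in self.subjects if s.group == "control"]

    @property
    def patients(self) -> list:
        return [s for s in self.subjects if s.group == "patient"]


# ---------------------------------------------------------------------------
# surfaces


def canonical_surface(space: TaskSpace, params: CohortParams | None = None) -> np.ndarray:
    """Deterministic group-level contrast surface shared by all controls."""
    params = params or CohortParams()
    opt_idx = []
    for name in params.optimal_tasks:
        if name in space.task_names:
            opt_idx.append(space.task_names.index(name) + 1)
    if not opt_idx:  # non-default spaces: put the ridge at the last task
        opt_idx = [space.n_tasks]
    coords = space.coordinate_array()
    t, d = coords[:, 0], coords[:, 1]
    ridge = np.max(
        [np.exp(-((t - j) ** 2) / (2 * params.ridge_width**2)) for j in opt_idx], axis=0
    )
    return params.baseline + params.ridge_amplitude * ridge + params.difficulty_slope * (d - 1)


def smooth_perturbation(
    space: TaskSpace, rng, amplitude: float, params: CohortParams | None = None
) -> np.ndarray:
    """Smooth zero-mean GP draw over the grid with unit marginal sd x amplitude."""
    if amplitude == 0:
        return np.zeros(space.n_conditions)
    params = params or CohortParams()
    rng = np.random.default_rng(rng)
    cfg = GPConfig(
        lengthscale_task=params.perturbation_lengthscale_task,
        lengthscale_difficulty=params.perturbation_lengthscale_difficulty,
        signal_variance=1.0,
    )
    coords = space.coordinate_array()
    k = kernel_matrix(coords, coords, cfg) + 1e-8 * np.eye(space.n_conditions)
    return amplitude * (np.linalg.cholesky(k) @ rng.standard_normal(space.n_conditions))


def sample_control_surface(
    space: TaskSpace, rng, params: CohortParams | None = None
) -> np.ndarray:
    """Canonical surface plus a small smooth individual perturbation."""
    params = params or CohortParams()
    return canonical_surface(space, params) + smooth_perturbation(
        space, rng, params.control_perturbation_sd, params
    )


def sample_patient_surface(
    space: TaskSpace, severity: float, rng, params: CohortParams | None = None
) -> np.ndarray:
    """Severity-attenuated canonical surface plus an idiosyncratic distortion.

    The canonical component is scaled by ``1 - attenuation * severity`` and a
    smooth perturbation with amplitude ``control_sd + severity * patient_sd``
    is added, so severity 0 reduces exactly to a control draw.
    """
    params = params or CohortParams()
    if not 0 <= severity <= 1:
        raise ValueError("severity must lie in [0, 1]")
    amp = params.control_perturbation_sd + severity * params.patient_perturbation_sd
    return (1 - params.patient_attenuation * severity) * canonical_surface(
        space, params
    ) + smooth_perturbation(space, rng, amp, params)


# ---------------------------------------------------------------------------
# block-level forward models


def _task_regressor(n_scans: int, onset_s: float, duration_s: float, tr: float) -> np.ndarray:
    from .glm import double_gamma_hrf

    scan_times = np.arange(n_scans) * tr
    boxcar = (
        (scan_times >= onset_s - 1e-9) & (scan_times < onset_s + duration_s - 1e-9)
    ).astype(float)
    return np.convolve(boxcar, double_gamma_hrf(tr))[:n_scans]


def ar1_noise(n: int, sd: float, phi: float, rng) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal standard deviation sd."""
    if sd == 0:
        return np.zeros(n)
    rng = np.random.default_rng(rng)
    innov_sd = sd * np.sqrt(1 - phi**2)
    e = np.empty(n)
    e[0] = rng.normal(0, sd)
    innov = rng.normal(0, innov_sd, size=n - 1)
    for i in range(1, n):
        e[i] = phi * e[i - 1] + innov[i - 1]
    return e


def simulate_block(
    subject: GroundTruthSubject,
    condition: Condition,
    mode: str,
    rng,
    space: TaskSpace,
    params: CohortParams | None = None,
    timing: BlockTiming | None = None,
):
    """Forward-model one task block.

    mode="direct" returns the scalar contrast f*(condition) + Gaussian noise
    (the fast path used by most simulations); mode="bold" returns the FPN and
    DMN time courses of the full 52 s iteration, from which the GLM engine
    must recover the contrast.
    """
    params = params or CohortParams()
    timing = timing or BlockTiming()
    space.validate(condition)
    rng = np.random.default_rng(rng)
    f = subject.true_value(space, condition)

    if mode == "direct":
        return float(f + rng.normal(0, subject.obs_noise_sd))
    if mode != "bold":
        raise ValueError(f"unknown mode {mode!r}; expected 'direct' or 'bold'")

    bold = params.bold
    tr = bold.tr_seconds
    n_scans = int(round(timing.total_s / tr))
    reg = _task_regressor(n_scans, timing.task_onset_s, timing.task_s, tr)
    t = np.arange(n_scans) * tr
    drift = bold.drift_per_second * (t - t.mean())
    amp_fpn = bold.fpn_baseline + 0.5 * f
    amp_dmn = bold.dmn_baseline - 0.5 * f
    fpn = amp_fpn * reg + drift + ar1_noise(n_scans, bold.noise_sd, bold.ar1_coefficient, rng)
    dmn = amp_dmn * reg + drift + ar1_noise(n_scans, bold.noise_sd, bold.ar1_coefficient, rng)
    return BlockTimecourses(
        fpn=fpn,
        dmn=dmn,
        tr_seconds=tr,
        task_onset_s=timing.task_onset_s,
        task_duration_s=timing.task_s,
    )


# ---------------------------------------------------------------------------
# behaviour


def accuracy_probability(
    subject: GroundTruthSubject,
    condition: Condition,
    space: TaskSpace,
    behaviour: BehaviourParams,
) -> float:
    """Closed-form per-trial probability of a correct response."""
    task = space.task_name(condition)
    if (task, condition.difficulty) in behaviour.always_correct:
        return 1.0
    eta = (
        behaviour.intercept
        + behaviour.group_effect * (subject.group == "patient")
        + behaviour.severity_slope * subject.severity
        + behaviour.difficulty_slope * (condition.difficulty - 1)
        + behaviour.task_offsets.get(task, 0.0)
        + subject.subject_intercept
    )
    floor = 1 / behaviour.n_categories_by_task.get(task, behaviour.n_categories_default)
    return float(floor + (1 - floor) / (1 + np.exp(-eta)))


def simulate_trials(
    subject: GroundTruthSubject,
    condition: Condition,
    n_trials: int,
    rng,
    space: TaskSpace,
    params: CohortParams | None = None,
    run: int = 1,
    block_index: int = 0,
) -> TrialRecord:
    """Simulate one block's answers, responses, correctness and RTs."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or CohortParams()
    beh = params.behaviour
    rng = np.random.default_rng(rng)
    task = space.task_name(condition)
    n_cat = beh.n_categories_by_task.get(task, beh.n_categories_default)
    categories = [f"cat{i}" for i in range(1, n_cat + 1)]
    answers = tuple(rng.choice(categories, size=n_trials))

    if task in beh.no_response_tasks:
        responses = tuple(NO_RESPONSE for _ in range(n_trials))
        correct = tuple(False for _ in range(n_trials))
        rts = tuple(float("nan") for _ in range(n_trials))
        return TrialRecord(
            subject.subject_id, run, block_index, condition, answers, responses, correct, rts
        )

    p = accuracy_probability(subject, condition, space, beh)
    is_correct = rng.random(n_trials) < p
    responses = []
    for ans, ok in zip(answers, is_correct):
        if ok:
            responses.append(ans)
        else:
            others = [c for c in categories if c != ans] or [NO_RESPONSE]
            responses.append(str(rng.choice(others)))
    log_mu = (
        beh.rt_log_mean
        + beh.rt_group_shift * (subject.group == "patient")
        + beh.rt_severity_shift * subject.severity
        + beh.rt_difficulty_shift * (condition.difficulty - 1)
    )
    rts = np.minimum(
        np.exp(rng.normal(log_mu, beh.rt_log_sd, size=n_trials)), beh.response_window_ms
    )
    return TrialRecord(
        subject.subject_id,
        run,
        block_index,
        condition,
        answers,
        tuple(responses),
        tuple(bool(c) for c in is_correct),
        tuple(float(r) for r in rts),
    )


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(
    n_controls: int = 14,
    n_patients: int = 11,
    n_runs: int = 2,
    master_seed: int = 0,
    space: TaskSpace | None = None,
    params: CohortParams | None = None,
) -> Cohort:
    """Reproducible synthetic cohort (defaults: 14 controls, 11 patients).

    Patient severity is Uniform(0.2, 1.0); lesion volume is log-normal and
    weakly correlated with severity. Controls carry severity 0 and lesion
    volume 0. All randomness derives from ``master_seed`` via named child
    streams, so the cohort is byte-identical across calls.
    """
    if n_controls < 1 or n_patients < 1 or n_runs < 1:
        raise ValueError("all cohort counts must be >= 1")
    from .task_space import build_task_space

    space = space or build_task_space()
    params = params or CohortParams()
    root = np.random.SeedSequence(master_seed)
    ss_surface, ss_traits = root.spawn(2)
    surface_rngs = ss_surface.spawn(n_controls + n_patients)
    traits = np.random.default_rng(ss_traits)

    subjects = []
    for i in range(n_controls):
        subjects.append(
            GroundTruthSubject(
                subject_id=f"C{i + 1:02d}",
                group="control",
                true_surface=sample_control_surface(space, surface_rngs[i], params),
                severity=0.0,
                obs_noise_sd=params.obs_noise_sd,
                lesion_volume=0.0,
                subject_intercept=float(
                    traits.normal(0, params.behaviour.subject_intercept_sd)
                ),
            )
        )
    lo, hi = params.severity_range
    for j in range(n_patients):
        severity = float(traits.uniform(lo, hi))
        z_sev = (severity - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12))
        rho = params.lesion_severity_correlation
        z = rho * z_sev + np.sqrt(1 - rho**2) * traits.standard_normal()
        lesion = float(np.exp(params.lesion_log_mean + params.lesion_log_sd * z))
        subjects.append(
            GroundTruthSubject(
                subject_id=f"P{j + 1:02d}",
                group="patient",
                true_surface=sample_patient_surface(
                    space, severity, surface_rngs[n_controls + j], params
                ),
                severity=severity,
                obs_noise_sd=params.obs_noise_sd
                * (1 + params.noise_severity_slope * severity),
                lesion_volume=lesion,
                subject_intercept=float(
                    traits.normal(0, params.behaviour.subject_intercept_sd)
                ),
            )
        )
    return Cohort(
        subjects=tuple(subjects), n_runs=n_runs, params=params, master_seed=master_seed
    )
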