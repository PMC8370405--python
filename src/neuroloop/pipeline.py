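"""Study orchestration: cohort -> closed-loop runs -> all analyses.

`run_study` replays the whole experiment on a synthetic cohort: every subject
undergoes two independently re-initialized optimization runs (fresh GP, fresh
seed stream), behaviour is simulated per sampled block, and the full analysis
battery (AUROC vs chance, reliability, dissimilarity/MDS/DBSCAN, behaviour
association, normalization) is computed and written as TSV tables and JSON
reports with a provenance record.

All randomness descends from one master seed through named child streams, so
any stage is independently reproducible and a rerun with the same
configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behaviour_table
from .cohort import BlockTiming, Cohort, CohortParams, generate_cohort, simulate_trials
from .gp import GPConfig
from .loop import DirectOracle, IncrementalGlmOracle, run_closed_loop
from .profiles import (
    behaviour_association,
    classical_mds,
    condition_adjusted_accuracy,
    dbscan_cluster,
    dissimilarity_matrix,
    group_dissimilarity_test,
    normalize_patients,
)
from .reliability import reliability_test
from .loop import predict_profile
from .task_space import build_task_space

__all__ = ["StudyConfig", "schedule_duration", "run_study"]


@dataclass(frozen=True)
class AnalysisParams:
    """Permutation/bootstrap counts and analysis thresholds."""

    n_perm_behaviour: int = 1000
    n_bootstrap: int = 10_000
    n_perm_reliability: int = 10_000
    n_perm_dissimilarity: int = 10_000
    n_perm_association: int = 50_000
    dbscan_eps: float = 0.3
    dbscan_min_pts: int = 3
    min_controls: int = 7


#: Reduced permutation counts for quick runs and tests.
FAST_ANALYSIS = AnalysisParams(
    n_perm_behaviour=200,
    n_bootstrap=500,
    n_perm_reliability=500,
    n_perm_dissimilarity=500,
    n_perm_association=1000,
)


@dataclass(frozen=True)
class StudyConfig:
    """Complete study specification with the experiment's default constants."""

    task_names: tuple = None  # default space if None
    n_difficulty: int = 3
    n_controls: int = 14
    n_patients: int = 11
    n_runs: int = 2
    n_iterations: int = 16
    n_burn_in: int = 4
    timing: BlockTiming = field(default_factory=BlockTiming)
    tr_seconds: float = 2.0
    equilibration_trs: int = 10
    mode: str = "direct"  # "direct" | "bold"
    gp: GPConfig = field(default_factory=GPConfig)
    cohort: CohortParams = field(default_factory=CohortParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    master_seed: int = 0

    def space(self):
        if self.task_names is None:
            return build_task_space(n_difficulty=self.n_difficulty)
        return build_task_space(tuple(self.task_names), self.n_difficulty)

    def to_dict(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x):
                return {
                    f.name: conv(getattr(x, f.name))
                    for f in dataclasses.fields(x)
                    if not f.name.startswith("_")
                }
            if isinstance(x, (tuple, list)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return conv(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load a config from YAML or JSON; unspecified fields keep defaults."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("timing", BlockTiming),
            ("gp", GPConfig),
            ("cohort", CohortParams),
            ("analysis", AnalysisParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "task_names" in kwargs and kwargs["task_names"] is not None:
            kwargs["task_names"] = tuple(kwargs["task_names"])
        return cls(**kwargs)


def schedule_duration(config: StudyConfig) -> float:
    """Scheduled run duration in minutes.

    (equilibration TRs x TR + n_iterations x iteration length) / 60; with the
    default timings one run lasts 14.2 min.
    """
    total_s = (
        config.equilibration_trs * config.tr_seconds
        + config.n_iterations * config.timing.total_s
    )
    return total_s / 60.0


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


#: order of the named child streams spawned from the master seed
_STAGE_NAMES = (
    "cohort",
    "loops",
    "trials",
    "behaviour",
    "reliability",
    "dissimilarity",
    "association",
)


def stage_seed_sequences(config: StudyConfig) -> dict:
    """Named per-stage SeedSequences derived from the master seed.

    Shared by run_study and the stage-wise CLI commands so that re-running a
    single stage from logged intermediates reproduces its outputs exactly.
    """
    children = np.random.SeedSequence(config.master_seed).spawn(len(_STAGE_NAMES))
    return dict(zip(_STAGE_NAMES, children))


def stage_seed(config: StudyConfig, stage: str) -> int:
    return _child_seed(stage_seed_sequences(config)[stage])


def _simulate_runs(config: StudyConfig, cohort: Cohort, ss_loops, ss_trials):
    """All closed-loop runs and per-block trials for every subject."""
    space = config.space()
    run_obs: dict[tuple, list] = {}
    trials = []
    loop_children = ss_loops.spawn(len(cohort.subjects) * config.n_runs)
    trial_children = ss_trials.spawn(len(cohort.subjects) * config.n_runs)
    k = 0
    for subject in cohort.subjects:
        for run in range(1, config.n_runs + 1):
            loop_ss = loop_children[k]
            trial_rng = np.random.default_rng(trial_children[k])
            k += 1
            oracle_ss, select_ss = loop_ss.spawn(2)
            if config.mode == "bold":
                oracle = IncrementalGlmOracle(
                    subject,
                    space,
                    oracle_ss,
                    cohort.params,
                    config.timing,
                    config.equilibration_trs,
                )
            else:
                oracle = DirectOracle(subject, space, oracle_ss, cohort.params)
            record = run_closed_loop(
                oracle,
                space,
                config.gp,
                n_iterations=config.n_iterations,
                n_burn_in=config.n_burn_in,
                rng_seed=select_ss,
                subject_id=subject.subject_id,
                run=run,
            )
            run_obs[(subject.subject_id, run)] = list(record.observations)
            for obs in record.observations:
                trials.append(
                    simulate_trials(
                        subject,
                        obs.condition,
                        cohort.params.behaviour.n_trials_per_block,
                        trial_rng,
                        space,
                        cohort.params,
                        run=run,
                        block_index=obs.iteration,
                    )
                )
    return run_obs, trials


def _observation_frame(run_obs, space) -> pd.DataFrame:
    rows = []
    for (subject_id, run), obs_list in run_obs.items():
        for obs in obs_list:
            rows.append(
                dict(
                    subject_id=subject_id,
                    run=run,
                    iteration=obs.iteration,
                    task_name=space.task_name(obs.condition),
                    difficulty=obs.condition.difficulty,
                    contrast_value=obs.value,
                    burn_in=obs.burn_in,
                )
            )
    return pd.DataFrame(rows)


def _trial_frame(trials, space) -> pd.DataFrame:
    rows = []
    for t in trials:
        for i in range(len(t.answers)):
            rows.append(
                dict(
                    subject_id=t.subject_id,
                    run=t.run,
                    block=t.block_index,
                    task_name=space.task_name(t.condition),
                    difficulty=t.condition.difficulty,
                    trial=i + 1,
                    answer=t.answers[i],
                    response=t.responses[i],
                    correct=t.correct[i],
                    rt_ms=t.rt_ms[i],
                )
            )
    return pd.DataFrame(rows)


def _per_condition_accuracy(trials, space, subject_ids) -> dict:
    """subject -> per-condition mean accuracy (NaN where never sampled)."""
    acc = {s: np.full(space.n_conditions, np.nan) for s in subject_ids}
    sums: dict = {}
    for t in trials:
        key = (t.subject_id, space.index_of(t.condition))
        tot, cnt = sums.get(key, (0.0, 0))
        sums[key] = (tot + t.accuracy, cnt + 1)
    for (subj, ci), (tot, cnt) in sums.items():
        if subj in acc:
            acc[subj][ci] = tot / cnt
    return acc


def load_observations(path, space) -> dict:
    """Read an observations TSV back into {(subject_id, run): [Observation]}."""
    from .gp import Observation
    from .task_space import Condition

    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[tuple, list] = {}
    for row in df.itertuples(index=False):
        cond = Condition(space.task_names.index(row.task_name) + 1, int(row.difficulty))
        out.setdefault((row.subject_id, int(row.run)), []).append(
            Observation(
                subject_id=row.subject_id,
                run=int(row.run),
                iteration=int(row.iteration),
                condition=cond,
                value=float(row.contrast_value),
                burn_in=bool(row.burn_in),
            )
        )
    return out


def load_trials(path, space) -> list:
    """Read a trials TSV back into TrialRecord blocks."""
    from .cohort import TrialRecord
    from .task_space import Condition

    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    keys = ["subject_id", "run", "block", "task_name", "difficulty"]
    for (subj, run, block, task, diff), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("trial")
        records.append(
            TrialRecord(
                subject_id=subj,
                run=int(run),
                block_index=int(block),
                condition=Condition(space.task_names.index(task) + 1, int(diff)),
                answers=tuple(grp.answer),
                responses=tuple(grp.response),
                correct=tuple(bool(c) for c in grp.correct),
                rt_ms=tuple(float(r) for r in grp.rt_ms),
            )
        )
    return records


def run_study(config: StudyConfig, outdir, fast: bool = False) -> dict:
    """Execute the full study and write all artifacts under ``outdir``.

    Returns a dict of in-memory results keyed by stage. ``fast`` swaps in
    reduced permutation counts for quick turnaround.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fast:
        config = replace(config, analysis=FAST_ANALYSIS)
    analysis = config.analysis
    space = config.space()

    seeds = stage_seed_sequences(config)
    ss_cohort = seeds["cohort"]
    ss_loops = seeds["loops"]
    ss_trials = seeds["trials"]
    ss_behaviour = seeds["behaviour"]
    ss_reliability = seeds["reliability"]
    ss_dissimilarity = seeds["dissimilarity"]
    ss_association = seeds["association"]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"study stage {name!r} failed: {exc}") from exc

    cohort = stage(
        "generate_cohort",
        generate_cohort,
        config.n_controls,
        config.n_patients,
        config.n_runs,
        _child_seed(ss_cohort),
        space,
        config.cohort,
    )
    groups = {s.subject_id: s.group for s in cohort.subjects}
    subject_ids = [s.subject_id for s in cohort.subjects]

    run_obs, trials = stage("closed_loop_runs", _simulate_runs, config, cohort, ss_loops, ss_trials)

    behaviour = stage(
        "behavior_stats",
        behaviour_table,
        trials,
        space,
        group="patient",
        groups=groups,
        n_permutations=analysis.n_perm_behaviour,
        n_bootstrap=analysis.n_bootstrap,
        rng_seed=_child_seed(ss_behaviour),
    )

    run1 = {s: run_obs[(s, 1)] for s in subject_ids}
    run2 = {s: run_obs[(s, 2)] for s in subject_ids} if config.n_runs >= 2 else None
    reliability = None
    if run2 is not None:
        reliability = stage(
            "reliability_stats",
            reliability_test,
            run1,
            run2,
            groups,
            space,
            config.gp,
            n_permutations=analysis.n_perm_reliability,
            rng_seed=_child_seed(ss_reliability),
        )

    # collapsed profiles over both runs
    profiles = {
        s: predict_profile(
            sum((run_obs[(s, r)] for r in range(1, config.n_runs + 1)), []),
            space,
            config.gp,
        )
        for s in subject_ids
    }
    dmat = stage("dissimilarity", dissimilarity_matrix, profiles)
    group_test = stage(
        "group_dissimilarity_test",
        group_dissimilarity_test,
        dmat,
        groups,
        n_permutations=analysis.n_perm_dissimilarity,
        rng_seed=_child_seed(ss_dissimilarity),
    )
    embedding = stage("classical_mds", classical_mds, dmat, 2, groups)
    clusters = stage(
        "dbscan", dbscan_cluster, dmat, analysis.dbscan_eps, analysis.dbscan_min_pts
    )

    accuracy = stage("condition_adjusted_accuracy", condition_adjusted_accuracy, trials)
    acc_vec = np.array([accuracy.get(s, np.nan) for s in subject_ids])
    lesions = np.array([s.lesion_volume for s in cohort.subjects])
    association = stage(
        "behaviour_association",
        behaviour_association,
        embedding.coordinates,
        acc_vec,
        lesions,
        [groups[s] for s in subject_ids],
        n_permutations=analysis.n_perm_association,
        rng_seed=_child_seed(ss_association),
    )

    per_cond_acc = _per_condition_accuracy(trials, space, subject_ids)
    normalization = stage(
        "normalize_patients",
        normalize_patients,
        {s: profiles[s] for s in subject_ids if groups[s] == "patient"},
        {s: profiles[s] for s in subject_ids if groups[s] == "control"},
        space,
        {s: per_cond_acc[s] for s in subject_ids if groups[s] == "patient"},
        {s: per_cond_acc[s] for s in subject_ids if groups[s] == "control"},
        analysis.min_controls,
    )

    # ------------------------------------------------------------------ write
    cfg_hash = config.config_hash()

    def write_tsv(df: pd.DataFrame, name: str):
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={cfg_hash}\n")
            df.to_csv(fh, sep="\t", index=False)

    subjects_df = pd.DataFrame(
        dict(
            subject_id=s.subject_id,
            group=s.group,
            severity=s.severity,
            lesion_volume=s.lesion_volume,
        )
        for s in cohort.subjects
    )
    cond_cols = [f"{space.task_name(c)}|{c.difficulty}" for c in space.conditions()]
    surfaces_df = pd.DataFrame(
        [s.true_surface for s in cohort.subjects], columns=cond_cols
    ).assign(subject_id=subject_ids)[["subject_id", *cond_cols]]
    profiles_df = pd.DataFrame(
        [profiles[s] for s in subject_ids], columns=cond_cols
    ).assign(subject_id=subject_ids)[["subject_id", *cond_cols]]
    dmat_df = pd.DataFrame(dmat.d, columns=list(dmat.subject_ids)).assign(
        subject_id=list(dmat.subject_ids)
    )[["subject_id", *dmat.subject_ids]]
    embed_df = pd.DataFrame(
        embedding.coordinates,
        columns=[f"coordinate_{i + 1}" for i in range(embedding.coordinates.shape[1])],
    ).assign(subject_id=subject_ids, cluster=clusters)

    write_tsv(subjects_df, "subjects")
    write_tsv(surfaces_df, "surfaces")
    write_tsv(_observation_frame(run_obs, space), "observations")
    write_tsv(_trial_frame(trials, space), "trials")
    write_tsv(behaviour, "behaviour_auroc")
    write_tsv(profiles_df, "profiles")
    write_tsv(dmat_df, "dissimilarity")
    write_tsv(embed_df, "embedding")
    write_tsv(association, "association")
    write_tsv(normalization, "normalization")

    reports = {
        "config_hash": cfg_hash,
        "schedule_duration_min": schedule_duration(config),
        "group_dissimilarity": dataclasses.asdict(group_test),
        "reliability": None
        if reliability is None
        else dict(
            per_subject_rho=reliability.per_subject_rho,
            group_median_z=reliability.group_median_z,
            p_value=reliability.p_value,
            n_permutations=reliability.n_permutations,
        ),
    }
    (outdir / "reports.json").write_text(json.dumps(reports, indent=2, sort_keys=True))
    provenance = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "master_seed": config.master_seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str)
    )

    return dict(
        config=config,
        cohort=cohort,
        run_obs=run_obs,
        trials=trials,
        behaviour=behaviour,
        reliability=reliability,
        profiles=profiles,
        dissimilarity=dmat,
        group_test=group_test,
        embedding=embedding,
        clusters=clusters,
        association=association,
        normalization=normalization,
        accuracy=accuracy,
    )
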