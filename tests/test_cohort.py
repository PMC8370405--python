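from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from neuroloop.cohort import (
    CohortParams,
    GroundTruthSubject,
    accuracy_probability,
    canonical_surface,
    generate_cohort,
    sample_control_surface,
    sample_patient_surface,
    simulate_block,
    simulate_trials,
)
from neuroloop.task_space import Condition


def test_zero_perturbation_gives_identical_control_surfaces(space):
    params = replace(CohortParams(), control_perturbation_sd=0.0)
    s1 = sample_control_surface(space, 1, params)
    s2 = sample_control_surface(space, 999, params)
    np.testing.assert_array_equal(s1, s2)
    np.testing.assert_array_equal(s1, canonical_surface(space, params))


def test_canonical_argmax_at_top_difficulty(space, cohort_params):
    surf = canonical_surface(space, cohort_params)
    best = space.conditions()[int(np.argmax(surf))]
    assert best.difficulty == space.n_difficulty
    assert space.task_name(best) in cohort_params.optimal_tasks


def test_difficulty_gradient_across_seeds(space, cohort_params):
    conds = space.conditions()
    easy = [i for i, c in enumerate(conds) if c.difficulty == 1]
    hard = [i for i, c in enumerate(conds) if c.difficulty == 3]
    for seed in range(100):
        surf = sample_control_surface(space, seed, cohort_params)
        assert surf[easy].mean() < surf[hard].mean()


def test_severity_zero_patient_equals_control_draw(space, cohort_params):
    p = sample_patient_surface(space, 0.0, 7, cohort_params)
    c = sample_control_surface(space, 7, cohort_params)
    np.testing.assert_allclose(p, c)


def test_severity_out_of_range_rejected(space, cohort_params):
    with pytest.raises(ValueError):
        sample_patient_surface(space, 1.5, 0, cohort_params)


def test_patient_surfaces_more_dissimilar_than_controls(space, cohort_params):
    def mean_pairwise_distance(surfaces):
        n = len(surfaces)
        d = [
            1 - spearmanr(surfaces[i], surfaces[j]).statistic
            for i in range(n)
            for j in range(i + 1, n)
        ]
        return np.mean(d)

    controls = [sample_control_surface(space, s, cohort_params) for s in range(50)]
    patients = [
        sample_patient_surface(space, 0.8, 1000 + s, cohort_params) for s in range(50)
    ]
    assert mean_pairwise_distance(patients) > mean_pairwise_distance(controls)


def test_attenuation_monotone_in_severity(space):
    # isolate the attenuation mechanism: no perturbation component
    params = replace(
        CohortParams(), control_perturbation_sd=0.0, patient_perturbation_sd=0.0
    )
    maxima = [
        sample_patient_surface(space, sev, 3, params).max()
        for sev in np.linspace(0, 1, 11)
    ]
    assert all(a > b for a, b in zip(maxima, maxima[1:]))


def test_direct_mode_noiseless_limit(space, cohort_params):
    surf = canonical_surface(space, cohort_params)
    subject = GroundTruthSubject("s", "control", surf, 0.0, 1e-12, 0.0)
    cond = Condition(3, 3)
    val = simulate_block(subject, cond, "direct", 0, space, cohort_params)
    assert val == pytest.approx(subject.true_value(space, cond), abs=1e-9)


def test_unknown_mode_rejected(space, cohort_params):
    subject = GroundTruthSubject(
        "s", "control", canonical_surface(space), 0.0, 0.1, 0.0
    )
    with pytest.raises(ValueError):
        simulate_block(subject, Condition(1, 1), "voxelwise", 0, space, cohort_params)


def test_forced_probability_one_gives_all_correct(space, cohort_params):
    subject = GroundTruthSubject(
        "s", "control", canonical_surface(space), 0.0, 0.1, 0.0
    )
    # Auditory Comprehension level 1 is configured always-correct
    cond = Condition(2, 1)
    rec = simulate_trials(subject, cond, 50, 0, space, cohort_params)
    assert all(rec.correct)
    assert rec.accuracy == 1.0


def test_simulated_accuracy_matches_logistic_probability(space, cohort_params):
    subject = GroundTruthSubject(
        "s", "patient", canonical_surface(space), 0.5, 0.1, 5.0
    )
    cond = Condition(5, 2)
    p = accuracy_probability(subject, cond, space, cohort_params.behaviour)
    rec = simulate_trials(subject, cond, 10_000, 1, space, cohort_params)
    assert rec.accuracy == pytest.approx(p, abs=0.02)


def test_patients_less_accurate_than_controls_at_every_difficulty(space, cohort_params):
    surf = canonical_surface(space, cohort_params)
    control = GroundTruthSubject("c", "control", surf, 0.0, 0.1, 0.0)
    patient = GroundTruthSubject("p", "patient", surf, 0.6, 0.1, 5.0)
    for difficulty in (1, 2, 3):
        cond = Condition(5, difficulty)  # Calculation: no special-case offsets
        acc_c = simulate_trials(control, cond, 1000, 2, space, cohort_params).accuracy
        acc_p = simulate_trials(patient, cond, 1000, 3, space, cohort_params).accuracy
        assert acc_p < acc_c


def test_chance_task_near_chance_level(space, cohort_params):
    surf = canonical_surface(space, cohort_params)
    control = GroundTruthSubject("c", "control", surf, 0.0, 0.1, 0.0)
    cond = Condition(4, 1)  # Verbal Learning, pinned at chance
    p = accuracy_probability(control, cond, space, cohort_params.behaviour)
    n_cat = cohort_params.behaviour.n_categories_default
    assert p == pytest.approx(1 / n_cat, abs=0.05)


def test_no_response_task_all_incorrect(space, cohort_params):
    surf = canonical_surface(space, cohort_params)
    subject = GroundTruthSubject("s", "control", surf, 0.0, 0.1, 0.0)
    rec = simulate_trials(subject, Condition(1, 2), 10, 0, space, cohort_params)
    assert not any(rec.correct)
    assert all(np.isnan(rec.rt_ms))


def test_cohort_defaults_and_invariants():
    cohort = generate_cohort(master_seed=5)
    assert len(cohort.controls) == 14
    assert len(cohort.patients) == 11
    for s in cohort.controls:
        assert s.severity == 0.0
        assert s.lesion_volume == 0.0
    for s in cohort.patients:
        assert 0.2 <= s.severity <= 1.0
        assert s.lesion_volume > 0
        assert s.obs_noise_sd > cohort.params.obs_noise_sd


def test_cohort_reproducible():
    a = generate_cohort(master_seed=11)
    b = generate_cohort(master_seed=11)
    for sa, sb in zip(a.subjects, b.subjects):
        assert sa.subject_id == sb.subject_id
        np.testing.assert_array_equal(sa.true_surface, sb.true_surface)
        assert sa.severity == sb.severity
        assert sa.lesion_volume == sb.lesion_volume


def test_severity_accuracy_link(space):
    """Severity must depress simulated accuracy across the default cohort."""
    cohort = generate_cohort(master_seed=2)
    rng = np.random.default_rng(0)
    sev, acc = [], []
    for s in cohort.subjects:
        accs = [
            simulate_trials(s, cond, 8, rng, space, cohort.params).accuracy
            for cond in space.conditions()
            if space.task_name(cond) not in cohort.params.behaviour.no_response_tasks
        ]
        sev.append(s.severity)
        acc.append(np.mean(accs))
    assert np.corrcoef(sev, acc)[0, 1] < 0
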