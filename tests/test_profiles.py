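import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr, ttest_ind

from neuroloop.profiles import (
    behaviour_association,
    classical_mds,
    condition_adjusted_accuracy,
    dbscan_cluster,
    dissimilarity_matrix,
    group_dissimilarity_test,
    median_absolute_deviation,
    modified_zscore,
    normalize_patients,
)


def brute_force_dbscan(d, eps, min_pts):
    """Independent density-reachability expansion (textbook algorithm)."""
    n = d.shape[0]
    labels = np.full(n, -1)
    neighbours = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbours]
    cluster = 0
    visited = set()
    for i in range(n):
        if i in visited or not core[i]:
            continue
        queue = [i]
        visited.add(i)
        labels[i] = cluster
        while queue:
            j = queue.pop()
            if core[j]:
                for k in neighbours[j]:
                    if labels[k] == -1:
                        labels[k] = cluster
                    if k not in visited and core[k]:
                        visited.add(k)
                        queue.append(k)
        cluster += 1
    return labels


# ---------------------------------------------------------------- dissimilarity


def test_dissimilarity_trivial_pairs(rng):
    base = rng.normal(size=21)
    profiles = {"a": base, "b": base.copy(), "c": base[::-1] * -1 + 5}
    m = dissimilarity_matrix(profiles)
    i, j = m.subject_ids.index("a"), m.subject_ids.index("b")
    assert m.d[i, j] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(m.d, m.d.T)
    assert np.all(np.diag(m.d) == 0)


def test_dissimilarity_rank_reversal_gives_two(rng):
    a = np.arange(21.0)
    m = dissimilarity_matrix({"a": a, "b": a[::-1]})
    assert m.d[0, 1] == pytest.approx(2.0)


def test_dissimilarity_matches_pairwise_oracle(rng):
    profiles = rng.normal(size=(5, 21))
    m = dissimilarity_matrix(profiles)
    for i in range(5):
        for j in range(5):
            expected = 0.0 if i == j else 1 - spearmanr(profiles[i], profiles[j]).statistic
            assert m.d[i, j] == pytest.approx(expected, abs=1e-12)
    assert m.d.min() >= 0 and m.d.max() <= 2


# ---------------------------------------------------------------- group test


def make_labels(n_c, n_p):
    ids = [f"c{i}" for i in range(n_c)] + [f"p{i}" for i in range(n_p)]
    return ids, {s: ("control" if s.startswith("c") else "patient") for s in ids}


def test_t_statistics_match_scipy_oracle(rng):
    profiles = rng.normal(size=(10, 21))
    ids, labels = make_labels(5, 5)
    m = dissimilarity_matrix(profiles, ids)
    res = group_dissimilarity_test(m, labels, n_permutations=10, rng_seed=0)
    is_c = np.array([labels[s] == "control" for s in ids])
    ci, pi = np.flatnonzero(is_c), np.flatnonzero(~is_c)
    cc = m.d[np.ix_(ci, ci)][np.triu_indices(5, 1)]
    pp = m.d[np.ix_(pi, pi)][np.triu_indices(5, 1)]
    cp = m.d[np.ix_(ci, pi)].ravel()
    assert res.t_within == pytest.approx(ttest_ind(cc, pp).statistic)
    assert res.t_between == pytest.approx(ttest_ind(cp, pp).statistic)


def test_group_test_detects_heterogeneous_patients(space, cohort_params, rng):
    from neuroloop.cohort import sample_control_surface, sample_patient_surface

    profiles, ids = [], []
    for i in range(10):
        profiles.append(sample_control_surface(space, 100 + i, cohort_params))
        ids.append(f"c{i}")
    for i in range(8):
        profiles.append(sample_patient_surface(space, 0.8, 200 + i, cohort_params))
        ids.append(f"p{i}")
    labels = {s: ("control" if s.startswith("c") else "patient") for s in ids}
    m = dissimilarity_matrix(np.array(profiles), ids)
    res = group_dissimilarity_test(m, labels, n_permutations=500, rng_seed=1)
    assert res.t_within < 0  # patients more dissimilar
    assert res.p_within < 0.05


def test_group_test_requires_two_per_group(rng):
    ids, labels = make_labels(1, 4)
    m = dissimilarity_matrix(rng.normal(size=(5, 21)), ids)
    with pytest.raises(ValueError):
        group_dissimilarity_test(m, labels, 10, 0)


# ---------------------------------------------------------------- MDS


def test_mds_zero_matrix():
    m = dissimilarity_matrix(np.tile(np.arange(21.0), (4, 1)))
    res = classical_mds(m, k=2)
    assert np.allclose(res.coordinates, 0.0)


def test_mds_reconstructs_collinear_distances():
    pos = np.array([0.0, 1.0, 3.5, 7.0])
    d = np.abs(pos[:, None] - pos[None, :])
    from neuroloop.profiles import DissimilarityMatrix

    m = DissimilarityMatrix(subject_ids=tuple(range(4)), d=d)
    res = classical_mds(m, k=3)
    assert res.coordinates.shape[1] == 1  # one positive eigenvalue only
    rec = np.abs(res.coordinates[:, 0][:, None] - res.coordinates[:, 0][None, :])
    np.testing.assert_allclose(rec, d, atol=1e-8)
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)


def test_mds_matches_skbio_pcoa(rng):
    skbio = pytest.importorskip("skbio")
    profiles = rng.normal(size=(8, 21))
    m = dissimilarity_matrix(profiles)
    res = classical_mds(m, k=2)
    pcoa = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(m.d))
    ref = pcoa.samples.values[:, :2]
    for j in range(2):
        col, refcol = res.coordinates[:, j], ref[:, j]
        assert min(
            np.abs(col - refcol).max(), np.abs(col + refcol).max()
        ) == pytest.approx(0.0, abs=1e-6)


def test_mds_orientation_patient_mean_nonnegative(rng):
    ids, labels = make_labels(6, 5)
    m = dissimilarity_matrix(rng.normal(size=(11, 21)), ids)
    res = classical_mds(m, k=2, orient_labels=labels)
    is_p = np.array([labels[s] == "patient" for s in ids])
    for j in range(res.coordinates.shape[1]):
        col = res.coordinates[:, j]
        assert col[is_p].mean() - col[~is_p].mean() >= -1e-12


# ---------------------------------------------------------------- DBSCAN


def test_dbscan_all_isolated_points_are_noise():
    from neuroloop.profiles import DissimilarityMatrix

    d = np.ones((5, 5)) * 10
    np.fill_diagonal(d, 0)
    m = DissimilarityMatrix(subject_ids=tuple(range(5)), d=d)
    labels = dbscan_cluster(m, eps=0.5, min_pts=2)
    assert np.all(labels == -1)


def test_dbscan_two_tight_groups():
    from neuroloop.profiles import DissimilarityMatrix

    n = 8
    d = np.full((n, n), 5.0)
    for grp in (range(4), range(4, 8)):
        for i in grp:
            for j in grp:
                d[i, j] = 0.05 if i != j else 0.0
    m = DissimilarityMatrix(subject_ids=tuple(range(n)), d=d)
    labels = dbscan_cluster(m, eps=0.3, min_pts=3)
    assert len(set(labels)) == 2
    assert -1 not in labels


def test_dbscan_matches_brute_force_oracle(rng):
    for trial in range(20):
        n = int(rng.integers(4, 11))
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        from neuroloop.profiles import DissimilarityMatrix

        m = DissimilarityMatrix(subject_ids=tuple(range(n)), d=d)
        eps = float(rng.uniform(0.3, 1.5))
        min_pts = int(rng.integers(2, 4))
        got = dbscan_cluster(m, eps, min_pts)
        want = brute_force_dbscan(d, eps, min_pts)
        # cluster ids may differ; compare partitions and noise sets
        assert np.array_equal(got == -1, want == -1)
        for lab in set(got) - {-1}:
            members = np.flatnonzero(got == lab)
            assert len({want[m_] for m_ in members}) == 1


# ------------------------------------------------------------- associations


def test_exact_anticorrelation_minimal_p(rng):
    coord = np.sort(rng.normal(size=12))
    acc = -coord
    lesion = np.abs(rng.normal(size=12)) + 1
    labels = ["control"] * 6 + ["patient"] * 6
    res = behaviour_association(coord, acc, lesion, labels, n_permutations=500, rng_seed=0)
    row = res[res.test == "accuracy_all_subjects"].iloc[0]
    assert row.r == pytest.approx(-1.0)
    assert row.p == pytest.approx(1 / 501, abs=1e-9)


def test_partial_correlation_matches_residual_oracle(rng):
    n = 9
    coord = rng.normal(size=n)
    lesion = rng.normal(size=n) + 5
    acc = -0.5 * coord + 0.3 * lesion + rng.normal(size=n) * 0.3
    labels = ["patient"] * n
    res = behaviour_association(coord, acc, lesion, labels, n_permutations=50, rng_seed=0)
    row = res[res.test == "accuracy_patients_partial_lesion"].iloc[0]

    def resid(y, x):
        A = np.column_stack([np.ones_like(x), x])
        return y - A @ np.linalg.lstsq(A, y, rcond=None)[0]

    expected = np.corrcoef(resid(coord, lesion), resid(acc, lesion))[0, 1]
    assert row.r == pytest.approx(expected, abs=1e-10)


def test_fdr_column_present_and_monotone(rng):
    coord = rng.normal(size=10)
    acc = rng.normal(size=10)
    lesion = np.abs(rng.normal(size=10)) + 1
    labels = ["control"] * 5 + ["patient"] * 5
    res = behaviour_association(coord, acc, lesion, labels, n_permutations=200, rng_seed=1)
    assert np.all(res.p_fdr >= res.p - 1e-12)


# ------------------------------------------------------------- normalization


def test_modified_zscore_worked_example():
    # controls {1..5}: median 3, MAD 1 -> z(5) = 0.6745 * 2 = 1.349
    z = modified_zscore(5.0, [1, 2, 3, 4, 5])
    assert z == pytest.approx(1.349, abs=1e-3)
    assert abs(z) < 1.96  # not an outlier under the criterion
    assert modified_zscore(3.0, [1, 2, 3, 4, 5]) == 0.0
    assert median_absolute_deviation([1, 2, 3, 4, 5]) == 1.0


def test_modified_zscore_degenerate_mad_is_nan():
    assert np.isnan(modified_zscore(2.0, [1.0, 1.0, 1.0]))


def test_normalize_median_patient_has_no_outliers(space, rng):
    controls = {f"c{i}": rng.normal(size=21) * 0.2 + np.arange(21) for i in range(10)}
    median_profile = np.median(np.array(list(controls.values())), axis=0)
    res = normalize_patients({"p0": median_profile}, controls, space)
    contrast = res[res.measure == "contrast"]
    assert not contrast.outlier.any()


def test_normalize_flags_injected_deviation(space, rng):
    controls = {f"c{i}": np.arange(21.0) + rng.normal(size=21) * 0.5 for i in range(10)}
    arr = np.array(list(controls.values()))
    profile = np.median(arr, axis=0).copy()
    mad = np.median(np.abs(arr[:, 7] - np.median(arr[:, 7])))
    profile[7] += 5 * mad
    res = normalize_patients({"p0": profile}, controls, space)
    contrast = res[res.measure == "contrast"]
    flagged = contrast[contrast.outlier]
    assert len(flagged) == 1
    assert flagged.iloc[0]["sign"] == "stronger"
    cond = space.conditions()[7]
    assert flagged.iloc[0]["task"] == space.task_name(cond)
    assert flagged.iloc[0]["difficulty"] == cond.difficulty


def test_accuracy_normalization_respects_min_controls(space, rng):
    controls = {f"c{i}": rng.normal(size=21) for i in range(10)}
    # accuracy defined for 8 controls at condition 0, only 5 at condition 1
    control_acc = {}
    for i in range(10):
        v = np.full(21, np.nan)
        if i < 8:
            v[0] = 0.8 + 0.01 * i
        if i < 5:
            v[1] = 0.7 + 0.01 * i
        control_acc[f"c{i}"] = v
    pat_acc = {"p0": np.where(np.arange(21) < 2, 0.5, np.nan)}
    res = normalize_patients(
        {"p0": rng.normal(size=21)},
        controls,
        space,
        patient_accuracy=pat_acc,
        control_accuracy=control_acc,
        min_controls=7,
    )
    acc = res[res.measure == "accuracy"].set_index(["task", "difficulty"])
    c0, c1 = space.conditions()[0], space.conditions()[1]
    assert np.isfinite(acc.loc[(space.task_name(c0), c0.difficulty), "modified_z"])
    assert acc.loc[(space.task_name(c1), c1.difficulty), "missing"]


def test_condition_adjusted_accuracy_corrects_for_sampling_mix():
    """Two subjects with identical skill but different task mixes should get
    similar adjusted scores even though raw means differ."""
    from neuroloop.cohort import TrialRecord
    from neuroloop.task_space import Condition

    def block(subject, cond, acc):
        n = 10
        k = int(acc * n)
        answers = tuple("A" for _ in range(n))
        responses = tuple("A" if i < k else "B" for i in range(n))
        return TrialRecord(
            subject, 1, 0, cond, answers, responses,
            tuple(r == a for r, a in zip(responses, answers)),
            tuple(700.0 for _ in range(n)),
        )

    easy, hard = Condition(5, 1), Condition(5, 3)
    trials = []
    # reference population setting per-condition means: easy 0.9, hard 0.5
    for i in range(4):
        trials.append(block(f"ref{i}", easy, 0.9))
        trials.append(block(f"ref{i}", hard, 0.5))
    trials += [block("mostly_easy", easy, 0.9), block("mostly_easy", easy, 0.9),
               block("mostly_easy", hard, 0.5)]
    trials += [block("mostly_hard", hard, 0.5), block("mostly_hard", hard, 0.5),
               block("mostly_hard", easy, 0.9)]
    adj = condition_adjusted_accuracy(trials)
    raw_easy = (0.9 + 0.9 + 0.5) / 3
    raw_hard = (0.5 + 0.5 + 0.9) / 3
    assert abs(adj["mostly_easy"] - adj["mostly_hard"]) < abs(raw_easy - raw_hard)
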