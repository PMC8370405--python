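"""Between-subject analysis of functional profiles.

Profiles (GP posterior means over the grid, both runs collapsed) are compared
with the Spearman correlation distance 1 - rho. Group structure is tested
with two-sample t statistics on sets of dissimilarity entries under a
label-permutation null; the geometry is visualized with classical MDS and
clustered with DBSCAN on the precomputed distances; the first principal
coordinate is related to behaviour by (partial) Pearson correlation with a
permutation null and Benjamini-Hochberg FDR; and individual patients are
referenced to the control distribution condition-by-condition with the
modified z-score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import DBSCAN
from statsmodels.stats.multitest import multipletests

from .task_space import TaskSpace

__all__ = [
    "DissimilarityMatrix",
    "GroupDissimilarityTest",
    "EmbeddingResult",
    "dissimilarity_matrix",
    "group_dissimilarity_test",
    "classical_mds",
    "dbscan_cluster",
    "behaviour_association",
    "modified_zscore",
    "normalize_patients",
    "condition_adjusted_accuracy",
]

OUTLIER_THRESHOLD = 1.96
MODIFIED_Z_SCALE = 0.6745


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric matrix of 1 - Spearman(profile_i, profile_j)."""

    subject_ids: tuple
    d: np.ndarray

    def submatrix(self, ids) -> np.ndarray:
        idx = [self.subject_ids.index(i) for i in ids]
        return self.d[np.ix_(idx, idx)]


@dataclass(frozen=True)
class GroupDissimilarityTest:
    """t statistics (controls minus patients direction) and one-sided p values.

    ``t_within`` compares the control-within entries with the patient-within
    entries; ``t_between`` compares the control-by-patient block with the
    patient-within entries. The alternative is that patients are more
    dissimilar, i.e. the lower tail of the permutation null.
    """

    t_within: float
    t_between: float
    p_within: float
    p_between: float
    n_permutations: int


@dataclass(frozen=True)
class EmbeddingResult:
    subject_ids: tuple
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    cluster_labels: np.ndarray | None = None


def dissimilarity_matrix(profiles, subject_ids=None) -> DissimilarityMatrix:
    """Pairwise Spearman correlation distance between subject profiles.

    ``profiles`` is (n_subjects, n_conditions) or a mapping id -> profile.
    Constant profiles yield NaN entries (undefined correlation).
    """
    if isinstance(profiles, dict):
        subject_ids = tuple(profiles)
        mat = np.asarray([profiles[s] for s in subject_ids], dtype=float)
    else:
        mat = np.asarray(profiles, dtype=float)
        subject_ids = tuple(subject_ids or range(len(mat)))
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 equal-length profiles")
    ranks = rankdata(mat, axis=1)
    centred = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centred @ centred.T) / np.outer(norms, norms)
    d = 1 - rho
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(subject_ids=subject_ids, d=d)


def _entry_sets(d: np.ndarray, is_control: np.ndarray):
    ci = np.flatnonzero(is_control)
    pi = np.flatnonzero(~is_control)
    cc = d[np.ix_(ci, ci)][np.triu_indices(ci.size, k=1)]
    pp = d[np.ix_(pi, pi)][np.triu_indices(pi.size, k=1)]
    cp = d[np.ix_(ci, pi)].ravel()
    return cc, pp, cp


def _two_sample_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> float:
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each entry set needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se = np.sqrt(va / na + vb / nb)
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    return float((a.mean() - b.mean()) / se)


def group_dissimilarity_test(
    matrix: DissimilarityMatrix,
    labels: dict,
    n_permutations: int = 10_000,
    rng_seed=None,
    welch: bool = False,
) -> GroupDissimilarityTest:
    """Label-permutation test that patients' profiles are more dissimilar.

    ``labels`` maps subject_id -> "control"/"patient". Both t statistics are
    oriented controls-minus-patients, so more-dissimilar patients push them
    negative; p values are lower-tailed with the +1 correction.
    """
    is_control = np.array([labels[s] == "control" for s in matrix.subject_ids])
    if is_control.sum() < 2 or (~is_control).sum() < 2:
        raise ValueError("need >= 2 subjects per group for within-group triangles")
    rng = np.random.default_rng(rng_seed)

    def stats(mask: np.ndarray) -> tuple[float, float]:
        cc, pp, cp = _entry_sets(matrix.d, mask)
        return _two_sample_t(cc, pp, welch), _two_sample_t(cp, pp, welch)

    t_within, t_between = stats(is_control)
    null_w = np.empty(n_permutations)
    null_b = np.empty(n_permutations)
    for i in range(n_permutations):
        null_w[i], null_b[i] = stats(rng.permutation(is_control))
    p_within = float((1 + np.sum(null_w <= t_within)) / (1 + n_permutations))
    p_between = float((1 + np.sum(null_b <= t_between)) / (1 + n_permutations))
    return GroupDissimilarityTest(
        t_within=t_within,
        t_between=t_between,
        p_within=p_within,
        p_between=p_between,
        n_permutations=n_permutations,
    )


def classical_mds(
    matrix: DissimilarityMatrix,
    k: int = 2,
    orient_labels: dict | None = None,
) -> EmbeddingResult:
    """Principal-coordinate embedding of the dissimilarity matrix.

    Double-centres -0.5 * J D^2 J, eigendecomposes, and keeps the top-k
    positive eigenvalues (descending); coordinates are eigenvectors scaled by
    the square root of their eigenvalue. If fewer than k eigenvalues are
    positive the embedding is truncated. Eigenvector sign is fixed by
    orienting each coordinate so the patient mean minus control mean is
    non-negative (when ``orient_labels`` is given), otherwise so the largest
    absolute loading is positive.
    """
    d = np.asarray(matrix.d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    k_eff = min(k, int(positive.sum()))
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])

    for j_ in range(k_eff):
        col = coords[:, j_]
        if orient_labels is not None:
            is_pat = np.array(
                [orient_labels[s] == "patient" for s in matrix.subject_ids]
            )
            direction = col[is_pat].mean() - col[~is_pat].mean()
        else:
            direction = col[np.argmax(np.abs(col))]
        if direction < 0:
            coords[:, j_] = -col
    return EmbeddingResult(
        subject_ids=matrix.subject_ids,
        coordinates=coords,
        eigenvalues=eigval[:k_eff],
    )


def dbscan_cluster(
    matrix: DissimilarityMatrix, eps: float = 0.3, min_pts: int = 3
) -> np.ndarray:
    """DBSCAN on the precomputed distances; label -1 marks outliers."""
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    model = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed")
    return model.fit_predict(matrix.d)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return float("nan")
    return float((a @ b) / denom)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _perm_pearson_p(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> tuple[float, float]:
    """One-sided (lower-tail) permutation p for Pearson r, shuffling y."""
    r_obs = _pearson(x, y)
    if np.isnan(r_obs):
        return r_obs, float("nan")
    xc = x - x.mean()
    xn = xc / np.sqrt((xc**2).sum())
    perm_idx = rng.permuted(np.tile(np.arange(y.size), (n_perm, 1)), axis=1)
    yp = y[perm_idx]  # (n_perm, n)
    ypc = yp - yp.mean(axis=1, keepdims=True)
    denom = np.sqrt((ypc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_null = (ypc @ xn) / denom
    p = float((1 + np.sum(r_null <= r_obs)) / (1 + n_perm))
    return r_obs, p


def behaviour_association(
    coordinates: np.ndarray,
    subject_accuracy: np.ndarray,
    lesion_volume: np.ndarray,
    labels: dict | list,
    subject_ids=None,
    n_permutations: int = 50_000,
    rng_seed=None,
) -> pd.DataFrame:
    """Correlate the first MDS coordinate with behaviour.

    Reports Pearson r over all subjects, over patients only, and the
    patients-only partial r controlling for lesion volume (correlation of OLS
    residuals). p values are one-sided (lower tail: worse behaviour at higher
    coordinate-1) from shuffling the behaviour vector against fixed
    coordinates, Benjamini-Hochberg corrected across the reported family.
    """
    coord1 = np.asarray(coordinates, dtype=float)
    if coord1.ndim == 2:
        coord1 = coord1[:, 0]
    acc = np.asarray(subject_accuracy, dtype=float)
    lesion = np.asarray(lesion_volume, dtype=float)
    if isinstance(labels, dict):
        subject_ids = subject_ids or list(labels)
        lab = np.array([labels[s] for s in subject_ids])
    else:
        lab = np.asarray(labels)
    if not (coord1.size == acc.size == lesion.size == lab.size):
        raise ValueError("all per-subject vectors must share one length")
    is_pat = lab == "patient"
    rng = np.random.default_rng(rng_seed)

    rows = []
    r, p = _perm_pearson_p(coord1, acc, n_permutations, rng)
    rows.append(dict(test="accuracy_all_subjects", n=int(acc.size), r=r, p=p))

    if is_pat.sum() >= 3:
        r, p = _perm_pearson_p(coord1[is_pat], acc[is_pat], n_permutations, rng)
        rows.append(dict(test="accuracy_patients", n=int(is_pat.sum()), r=r, p=p))

        # partial correlation: residualize both on lesion volume; permute the
        # behaviour vector, re-residualizing it each time
        xr = _residualize(coord1[is_pat], lesion[is_pat])
        y_pat = acc[is_pat]
        r_obs = _pearson(xr, _residualize(y_pat, lesion[is_pat]))
        count = 0
        for _ in range(n_permutations):
            yp = rng.permutation(y_pat)
            if _pearson(xr, _residualize(yp, lesion[is_pat])) <= r_obs:
                count += 1
        p = float((1 + count) / (1 + n_permutations))
        rows.append(
            dict(test="accuracy_patients_partial_lesion", n=int(is_pat.sum()), r=r_obs, p=p)
        )

    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_fdr"] = np.nan
    if valid.any():
        out.loc[valid, "p_fdr"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


def median_absolute_deviation(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def modified_zscore(value: float, control_values) -> float:
    """0.6745 * (value - median(controls)) / MAD(controls); NaN if MAD is 0."""
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 2:
        raise ValueError("need >= 2 control values")
    mad = median_absolute_deviation(controls)
    if mad == 0:
        return float("nan")
    return float(MODIFIED_Z_SCALE * (value - np.median(controls)) / mad)


def _normalize_block(
    patient_values: pd.DataFrame | np.ndarray,
    control_values: np.ndarray,
    patient_ids,
    space: TaskSpace,
    measure: str,
    min_controls: int = 0,
) -> list[dict]:
    rows = []
    pv = np.asarray(patient_values, dtype=float)
    cv = np.asarray(control_values, dtype=float)
    for ci, cond in enumerate(space.conditions()):
        col = cv[:, ci]
        col = col[np.isfinite(col)]
        enough = col.size > min_controls if min_controls else col.size >= 2
        for pi, pid in enumerate(patient_ids):
            val = pv[pi, ci]
            if not enough or not np.isfinite(val):
                z = float("nan")
            else:
                z = modified_zscore(val, col)
            outlier = bool(np.isfinite(z) and abs(z) > OUTLIER_THRESHOLD)
            sign = "none"
            if outlier:
                sign = "stronger" if z > 0 else "weaker"
            rows.append(
                dict(
                    measure=measure,
                    patient=pid,
                    task=space.task_name(cond),
                    difficulty=cond.difficulty,
                    modified_z=z,
                    outlier=outlier,
                    sign=sign,
                    missing=not (enough and np.isfinite(val)),
                )
            )
    return rows


def normalize_patients(
    patient_profiles,
    control_profiles,
    space: TaskSpace,
    patient_accuracy=None,
    control_accuracy=None,
    min_controls: int = 7,
) -> pd.DataFrame:
    """Modified z-score of each patient against controls, per condition.

    ``*_profiles`` map subject_id -> profile vector (contrast predictions at
    every condition). Optional ``*_accuracy`` carry per-condition accuracy
    with NaN where a subject never sampled the condition; those are
    normalized only where strictly more than ``min_controls`` control values
    exist, otherwise the condition is reported as missing. Outliers are
    flagged at |z| > 1.96 with a stronger/weaker sign.
    """
    if not control_profiles:
        raise ValueError("control set must be non-empty")
    pat_ids = list(patient_profiles)
    rows = _normalize_block(
        np.asarray([patient_profiles[p] for p in pat_ids]),
        np.asarray([control_profiles[c] for c in control_profiles]),
        pat_ids,
        space,
        measure="contrast",
    )
    if patient_accuracy is not None and control_accuracy is not None:
        acc_ids = list(patient_accuracy)
        rows += _normalize_block(
            np.asarray([patient_accuracy[p] for p in acc_ids]),
            np.asarray([control_accuracy[c] for c in control_accuracy]),
            acc_ids,
            space,
            measure="accuracy",
            min_controls=min_controls,
        )
    return pd.DataFrame(rows)


def condition_adjusted_accuracy(trials) -> pd.Series:
    """Per-subject mean accuracy adjusted for which conditions were sampled.

    Because the adaptive loop gives every subject a different task mix, a raw
    mean is confounded by condition difficulty. The stand-in used here is the
    grand mean plus the average of the subject's deviations from the
    per-condition mean accuracies.
    """
    df = pd.DataFrame(
        dict(
            subject=t.subject_id,
            condition=(t.condition.task_index, t.condition.difficulty),
            accuracy=t.accuracy,
        )
        for t in trials
    )
    if df.empty:
        raise ValueError("no trial records supplied")
    grand = df["accuracy"].mean()
    cond_means = df.groupby("condition")["accuracy"].transform("mean")
    df["deviation"] = df["accuracy"] - cond_means
    return grand + df.groupby("subject")["deviation"].mean()
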