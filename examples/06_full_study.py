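"""The full study pipeline on a default synthetic cohort.

Generates 14 controls and 11 patients, runs two independently re-initialized
closed-loop optimization runs per subject, and executes every analysis stage
(behavioural AUROC, reliability, dissimilarity/MDS/DBSCAN, behaviour
association, normalization), writing all tables and reports to ./study_out.
Uses the reduced permutation profile so it finishes in seconds.
"""

from neuroloop.pipeline import StudyConfig, run_study

config = StudyConfig(master_seed=1)
results = run_study(config, "study_out", fast=True)

rel = results["reliability"]
print("reliability:", {g: round(p, 4) for g, p in rel.p_value.items()})
gt = results["group_test"]
print(f"dissimilarity: t_within = {gt.t_within:.2f}, p = {gt.p_within:.4f}")
assoc = results["association"]
print(assoc[["test", "n", "r", "p", "p_fdr"]].to_string(index=False))
n_out = int((results["clusters"] == -1).sum())
print(f"DBSCAN outliers: {n_out} of {len(results['clusters'])} subjects")
print("artifacts written to ./study_out (TSV tables + JSON reports)")
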