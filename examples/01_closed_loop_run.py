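"""One subject's closed-loop optimization run.

Builds the default 7x3 task space, draws a synthetic control subject, and
runs 16 iterations of the loop: 4 random burn-in blocks, then GP-UCB
selection. Prints the sampled trajectory and where the final Bayesian
prediction places the subject's optimal condition; the contrast values are
FPN>DMN beta differences in arbitrary units, and the loop should concentrate
on the high-contrast ridge of the surface.
"""

import numpy as np

import neuroloop as nl

space = nl.build_task_space()
gp = nl.GPConfig()
cohort = nl.generate_cohort(n_controls=1, n_patients=1, master_seed=7)
subject = cohort.controls[0]

record = nl.run_closed_loop(
    nl.DirectOracle(subject, space, 1, cohort.params),
    space,
    gp,
    rng_seed=2,
    subject_id=subject.subject_id,
)

print("iter  condition                            contrast")
for obs in record.observations:
    tag = "  (burn-in)" if obs.burn_in else ""
    print(f"{obs.iteration:4d}  {space.condition_label(obs.condition):35s} {obs.value:+.3f}{tag}")

profile = nl.predict_profile(record.observations, space, gp)
best = space.conditions()[int(np.argmax(profile))]
truth = space.conditions()[int(np.argmax(subject.true_surface))]
print(f"\npredicted optimum: {space.condition_label(best)}")
print(f"true optimum:      {space.condition_label(truth)}")
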