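"""Generate a small synthetic cohort and inspect the task structure.

The simulator reproduces the helping-under-threat paradigm: 8 runs of 18
trials, distal/imminent blocks, three threat levels, help/no-help decisions
with the 70% both-shocked contingency, and post-scan ratings.
"""

import threathelp as th

exp = th.simulate_experiment(n_subjects=5, seed=7)

print("trials per subject:", len(exp.schedule) // 5)
print("\nimminence x level cell counts (subject 1):")
s1 = exp.schedule[exp.schedule.subject_id == 1]
print(s1.groupby(["imminence", "level"]).size().unstack())

merged = exp.outcomes.merge(exp.decisions, on=["subject_id", "global_trial_id"])
helped = merged[merged.response == "help"]
print(
    f"\nboth shocked after helping: {helped.participant_shocked.mean():.2f} "
    "(contingency is 0.70)"
)

print("\ndistress rating means by condition (higher = more perceived distress):")
rat = exp.ratings.distress.merge(exp.schedule, on=["subject_id", "global_trial_id"])
print(rat.groupby(["imminence", "level"])["distress_rating"].mean().unstack().round(2))
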