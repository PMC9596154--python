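"""Build one subject's neural and behavioral RDMs for the distal condition.

A neural RDM entry (i, j) is 1 - Pearson r between the voxel patterns of
trials i and j; behavioral RDMs are absolute differences between the
subject's own ratings (perceived distress of the co-participant per clip,
or felt threat per cue image).
"""

import numpy as np

import threathelp as th

sched = th.generate_schedule(th.TaskDesign(), n_subjects=1, seed=3)
ratings = th.generate_ratings(sched, seed=3)
params = th.NeuralParams(rois=("amygdala_left",), n_voxels=80)
patterns = th.generate_roi_patterns(sched, ratings, params, seed=3)

distal = sched[sched.imminence == "distal"]
trial_ids = distal["global_trial_id"].to_numpy()

neural = th.neural_rdm(patterns[(1, "amygdala_left")].subset(trial_ids), "distal")
print(f"neural RDM: {neural.n} x {neural.n}, entries in "
      f"[{neural.matrix.min():.3f}, {neural.matrix.max():.3f}] (range is [0, 2])")

threat_vals = th.trial_threat_ratings(sched, ratings.threat, "distal")
threat_rdm = th.rating_rdm(threat_vals.to_numpy(), trial_ids, "distal", "threat")
print("threat RDM distinct dissimilarities:",
      np.unique(threat_rdm.matrix).tolist(),
      "(few values: trials share one cue rating per threat level)")

sim_t = th.second_order_similarity(neural, threat_rdm)
print(f"\nsecond-order Kendall tau-a (neural vs threat): {sim_t.tau:.3f} "
      f"over {sim_t.n_pairs} trial pairs")
print("positive tau: trials that feel similarly threatening also evoke "
      "similar voxel patterns")
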