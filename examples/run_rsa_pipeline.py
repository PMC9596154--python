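"""Full similarity analysis on a synthetic cohort.

Second-order similarities (Kendall tau-a between each region's neural RDM
and the threat / distress model RDMs, per imminence condition) enter one
linear model per region predicting the subject's overall helping %; slope
p-values are pooled across regions for Benjamini-Hochberg FDR control.

The cohort plants a brain-behavior link: left-amygdala threat coding
drives helping propensity, so its threat-similarity slope should be
positive and survive FDR.
"""

import threathelp as th

exp = th.simulate_experiment(n_subjects=30, seed=42)

res = th.run_rsa(
    exp.patterns,
    exp.schedule,
    exp.ratings.distress,
    exp.ratings.threat,
    exp.decisions,
    roi_list=list(th.DEFAULT_ROI_LIST),
)

print("left amygdala model (helping % on similarity predictors):")
la = res.models[res.models.roi == "amygdala_left"]
print(la[["term", "beta", "se", "t", "p", "p_fdr"]].round(4).to_string(index=False))

sig = res.models[res.models.significant]
print("\nFDR-significant coefficients across all 13 models:")
print(sig[["roi", "term", "beta", "p_fdr"]].round(4).to_string(index=False)
      if len(sig) else "  none")

print("\npredominance (does any region represent threat vs distress more strongly?):")
print(res.predominance[res.predominance.significant][["roi", "condition", "direction"]]
      .to_string(index=False)
      if res.predominance.significant.any() else "  no region shows predominance")
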