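"""Generate a calibrated synthetic cancer-pain telemedicine cohort.

The default calibration reproduces the study population's margins: 218
patients, ~37% with breakthrough cancer pain, ~61% on >60 mg/day morphine
equivalent, ~90.6% metastatic, a roughly 50/50 split between one and more
than one tele-visit, and odds of a second tele-visit that fall 3% per year
of age.
"""

import telepain as tp

spec = tp.default_spec(n=218, seed=1)
cohort = tp.sample_cohort(spec, seed=1)

print(f"patients: {len(cohort)}")
print(f"BTcP prevalence:        {cohort['btcp'].mean():.3f}   (calibration 0.372)")
print(f"MED>60 prevalence:      {cohort['med_gt60'].mean():.3f}   (calibration 0.610)")
print(f"metastatic prevalence:  {cohort['metastatic'].mean():.3f}   (calibration 0.906)")
print(f"one-visit fraction:     {(cohort['outcome'] == 'one').mean():.3f}   (calibration 0.495)")
print(f"tele-visits mean / median: {cohort['n_televisits'].mean():.2f} / {cohort['n_televisits'].median():.0f}")
print()
print("Per-outcome summary (first rows):")
print(tp.summarize(cohort).head(6).to_string(index=False))
print()
print("Sample prevalences fluctuate binomially around the calibrated margins;")
print("the outcome column is the dichotomized tele-visit count (one vs more).")
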