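"""Synthetic vulnerability study: cohort, peeling augmentation, and the
adaptive S1-S4 programmed-stimulation protocol.

Synthesizes a cohort of virtual patients, expands it by relabeling the
outermost 1/2/5/10 ischemic layers as healthy tissue, runs the 17-site
vulnerability protocol (surrogate backend) on every model, and prints the
per-peel-level summary: inducibility declines as the substrate shrinks.
"""

from reentryforge.population import synthesize_study

study = synthesize_study(n_patients=12, seed=42)

s = study.summary
print(f"tested segments: {s.tested_segments}, "
      f"arrhythmic: {s.arrhythmic_segments} "
      f"(ratio {s.ratio:.3f})\n")

cols = ["peel_level", "n_patients", "mean_ischemia_pct",
        "pct_patients_with_reentry", "pct_segments_with_reentry",
        "mean_reentries_per_model"]
print(s.per_level[cols].round(2).to_string(index=False))
print("\nEach row is one peel level (0 = the baseline cohort); the "
      "percentage of inducible segments falls as layers are removed, "
      "because a smaller, less graded ischemic substrate supports fewer "
      "reentrant circuits.")
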