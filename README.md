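# reentryforge

Simulation-supported arrhythmia-risk assessment for post-infarction
ventricles, at desk scale. The package reproduces, on fully synthetic
geometries, a combined in-silico + machine-learning methodology:

1. **Graded ischemic ventricular models.** Synthetic myocardial domains
   (2D sheets for speed, voxelized truncated-ellipsoid LV shells for 3D
   demonstrations) carry an embedded ischemic region divided into 10–27
   concentric layers by distance from its outer surface. Across layers,
   extracellular potassium rises linearly from 7.5 to 10 mM, the inner
   half of the layers has a 30% reduction of I_Na and I_CaL (20% in the
   outer half), a fraction f_ATP = 0.0049 of ATP-sensitive K⁺ channels is
   open, and tissue conductivity is reduced by 40%.
2. **Layer-peeling augmentation.** Relabeling the outermost 1, 2, 5 and
   10 layers as healthy tissue turns each virtual patient into a family
   of models with shrinking infarcts — a biophysically grounded data
   augmentation.
3. **Monodomain vulnerability testing.** A finite-volume monodomain
   solver (ten Tusscher–Panfilov 2006 epicardial ionic model, Rush–Larsen
   gating, anisotropic conductivity from rule-based fibers) drives an
   adaptive programmed-stimulation protocol at 17 AHA left-ventricular
   sites: five S1 beats at 350 ms, then S2/S3/S4 extrastimuli tightened
   in 10 ms steps until reentry or loss of capture, with a 2000 ms
   observation window classified as NR / UR / R (no, unsustained,
   sustained reentry). A documented substrate-propensity surrogate
   backend makes population-scale studies tractable on one CPU.
4. **Geometric-feature risk classification.** Four features per
   (model, AHA segment) — segment volume, segment ischemic %, total
   myocardial volume, total ischemic volume — feed seven classifiers
   (kNN k=5, RBF-SVM C=2, logistic regression, depth-3 tree, gradient
   boosting, 3- and 4-hidden-layer MLPs) over 100 random 70/30 splits,
   with accuracy / precision / sensitivity / average precision / ROC AUC
   and one-sided t/F tests comparing baseline vs augmented populations.

## Worked example

```python
from reentryforge.population import synthesize_study
from reentryforge.ml import ExperimentConfig, run_experiment, compare_populations

study = synthesize_study(n_patients=12, seed=42)
print(study.summary.per_level[["peel_level", "pct_segments_with_reentry"]])
```

prints the vulnerability trend across peel levels (seed 42):

```
 peel_level  pct_segments_with_reentry
          0                       7.84
          1                       7.35
          2                       5.39
          5                       3.43
         10                       1.60
```

— inducibility falls monotonically as outer ischemic layers are removed.
Continuing,

```python
cfg = ExperimentConfig(n_runs=20)
pr_b, _ = run_experiment(study.baseline_dataset, cfg, seed=42)
pr_a, _ = run_experiment(study.augmented_dataset, cfg, seed=42)
print(compare_populations(pr_b, pr_a)[["model", "mean_baseline", "mean_augmented"]])
```

shows every classifier's mean test accuracy rising (0.91–0.94 baseline
to 0.95–0.97 augmented on this small synthetic cohort) with a roughly
threefold reduction in run-to-run spread when the peel-augmented models
are added — the directional augmentation claim.
The `examples/` directory has one narrative script per capability
(geometry, single-cell restitution, tissue conduction, the vulnerability
study, risk classification); each prints its numbers with a line on what
they mean. A thin CLI mirrors the pipeline stages
(`reentryforge geom|grade|protocol|ml|pipeline|fixtures`).

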