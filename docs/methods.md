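# Methods

## Scope and model overview

reentryforge implements a complete, desk-scale version of a
simulation-supported arrhythmia-risk methodology for post-infarction
ventricles. Patient-derived anatomy is replaced by synthetic geometries;
everything downstream of anatomy — ischemic layer grading, layer-peeling
augmentation, monodomain programmed stimulation, geometric features, and
the classifier harness — is implemented in full and is
representation-agnostic (the same code paths run on 2D sheets and on
voxelized LV shells).

## Geometry

Two generators are provided. The 2D slab is a structured quad grid
(spacing 0.1–0.5 mm) with a circular ischemic subdomain; the 3D shell is
a voxelized truncated half-ellipsoid (base plane open, apex closed) with
the inner surface offset from the outer by the wall thickness. AHA
17-segment labels on shells follow the standard construction — long-axis
thirds with 6/6/4 circumferential sectors plus an apex cap; on slabs a
deterministic 17-tile rectangular layout (3 rows × 6 columns with the
last two tiles of the top row merged) substitutes for the polar map so
the whole pipeline runs on 2D fixtures; the substitution is flagged in
the geometry metadata. Fibers follow a rule-based linear transmural
rotation (default +60° endo to −60° epi); the transmural coordinate on
shells is found per voxel by bisection on the interpolating ellipsoid
family. Geometries serialize to VTK legacy ASCII unstructured grids with
cell data `region_label`, `segment_id`, `fiber_angle`, `element_volume`
plus numeric metadata in the FIELD block; the writer is deterministic
(fixed float formatting), so identical inputs give byte-identical files.

## Ischemic layers and grading

Ischemic elements are ranked by distance to the nearest healthy element
(a KD-tree query) and binned into L equal-width distance bins — an
equal-count option exists — giving concentric layers, 1 at the rim to L
in the core; empty bins are compressed out with a warning. Grading
across layers: K_o interpolates linearly from 7.5 mM (layer 1) to 10 mM
(layer L; a single layer is treated as core); the innermost 50% of
layers (ties to inner: inner iff k > floor(L/2)) scale I_Na and I_CaL by
0.70, the outer layers by 0.80; f_ATP = 0.0049 and the 40% conductivity
reduction apply uniformly over all ischemic layers. Peeling k layers
relabels layers 1..k as healthy and re-indexes the rest, so re-grading
regenerates a normal-to-core gradient (the new rim returns to 7.5 mM and
the 0.80 scales); peel(a) then peel(b) equals peel(a+b) exactly, and a
model peeled to nothing (k ≥ L) is excluded from populations.

## Ionic model

The cell model is the ten Tusscher–Panfilov 2006 epicardial variant (19
states), verified in the test suite against an independent transcription
of the published equations at 1e-6 relative tolerance. The published
sqrt(K_o/5.4) factors on I_K1 and I_Kr are retained (they matter here
because K_o varies). Ischemia enters through per-cell K_o, I_Na/I_CaL
scale factors, and a Ferrero-type ATP-sensitive current
I_KATP = g_KATP · f_ATP · (K_o/5.4)^0.24 · (V − E_K). The reference
conductance g_KATP = 1.5 (model units) is a calibration, not a
literature value: it was chosen once so that f_ATP = 0.0049 shortens the
healthy APD90 by ≈18% (a 10–25% target band), and is stored in the
parameter preset.

The steep-restitution preset sets G_Kr = 0.172, G_Ks = 0.441,
G_pCa = 0.8666, G_pK = 0.00219 (the published restitution-variant
family); with these values the measured maximum S1S2 restitution slope
is 1.81 at a 1000 ms drive train (1.82 at 600 ms). A multiplier on the
ICaL f-gate time constant is exposed as an additional knob but defaults
to 1, because the unmodified time constant is what reproduces the
published slope of 1.8 in this implementation.

Integration is Rush–Larsen for the 12 voltage gates and forward Euler
for voltage, concentrations and the SR release variable, dt = 0.02 ms
default (0.05 ms hard bound). APD90 is measured from the maximum-dV/dt
upstroke to 90% repolarization toward the pre-stimulus diastolic
voltage. The S1S2 restitution protocol paces to approximate steady state
(19 drive beats by default), stores the end-of-drive state, and restarts
from it for every S2, so the diastolic-interval grid order cannot affect
the curve; S2 responses that fail to overshoot 0 mV are treated as
non-captured rather than as points on the curve.

## Tissue model

Monodomain reaction–diffusion on the element grid:
∂V/∂t = ∇·(D∇V) − I_ion + I_stim, with D built per element from the
fiber angle as R diag(D_l, D_t) Rᵀ. Conductivities (defaults
σ_l = 0.136, σ_t = 0.0176 S/m, the harmonic-mean monodomain values
commonly used for human ventricle) convert to diffusivities via
D = σ/(β·C_m) with β·C_m = 1400 µF/cm³. Space uses a conservative
cell-centred finite-volume stencil: harmonic-mean face diffusivities on
the axis terms and flux-form central differences for the in-plane cross
terms, so rows and columns of the operator sum to zero and the spatial
mean is conserved under pure diffusion (no-flux boundaries). Time uses
operator splitting with automatic sub-stepping of the explicit diffusion
step whenever dt exceeds dx²/(2·dim·D_max).

At the default dx = 0.25 mm the longitudinal CV is ≈0.56 mm/ms and still
carries ≈10% discretization error (the convergence test shows <2% change
when halving from 0.125 mm); ratios of CVs at the same resolution cancel
most of it, which is why the 40%-reduction check is formulated as a CV
ratio against √0.6.

Stimuli are rectangular current pulses into an electrode footprint
(≈1 mm patch). The nominal electrode amplitude (100 µA/cm², 10 ms)
couples to the membrane through a conversion factor of 0.1 — calibrated
once so the default pulse is comfortably suprathreshold from rest yet
does not drive voltage unphysically when delivered into refractory
tissue. Activation events are upward −40 mV crossings with a 50 ms
per-element lockout.

## Vulnerability protocol

The adaptive cascade: 5 S1 at 350 ms cycle length; S2 first at 200 ms
coupling, decremented by 10 ms per attempt; on reentry the site's
protocol stops; on capture failure the last captured S2 is fixed and S3
starts at 250 ms (then S4 likewise); a hard 100 ms coupling floor bounds
runtime. Capture means an activation ≥5 mm from the electrode within
100 ms of the stimulus. Each delivered premature stimulus is observed
for 2000 ms; re-excitation (any element activating twice after a 50 ms
post-stimulus latency) that persists into the final 200 ms of the window
is sustained reentry (R), earlier extinction is unsustained (UR),
otherwise NR. The 200 ms sustained-tail and 50 ms latency are
configurable choices — the outcome taxonomy itself does not pin them
down. Both UR and R count as "arrhythmia" for the downstream labels.

The state machine is backend-agnostic. The tissue backend re-simulates
the full train per attempt and is intended for fixture-scale geometries.
The surrogate backend replaces the PDE solve with a documented
substrate-propensity model: per (patient, segment) a latent score
z = 0.18·√(segment ischemic %) + 0.50·√(global ischemic %) + u_patient +
ε_site (u ~ N(0, 0.45), ε ~ N(0, 0.30), seeded), plus a site refractory
period ERP ~ N(150, 12) ms that bounds capture; an attempt at stage k
with coupling ci induces iff z exceeds
3.4 − 0.004·(200 − ci) − 0.25·(k−1), and the margin over threshold
decides R vs UR. The square roots saturate the segment term so a core
segment that stays 100% ischemic after peeling cannot dominate; patient
effect, site noise and ERP are shared across a patient's peel variants,
so peeling moves scores only through the shrinking substrate terms and
vulnerability declines monotonically — the structure, not a per-seed
tuning. The constants were calibrated once against the cohort-level
vulnerability pattern the generator is required to emulate (≈22% of
segments and ≈57% of patients inducible at baseline, declining strongly
by 10 peeled layers).

## Synthetic cohort

The default cohort emulates the clinical population's ischemic-burden
distribution: 30 patients, global ischemic fraction lognormal with mean
10.8% and SD 10.5% (clipped to [1.5, 40]%), sheet dimensions varying
±10% between patients (myocardial volume varies), disc centre jittered,
and the layer count set by disc radius in elements, clipped to 10–27;
small infarcts that cannot support the requested count are reduced
automatically. What the generator does **not** emulate: irregular infarct
shapes, transmural heterogeneity, 3D wall architecture, and any direct
electrophysiological coupling between substrate and outcome beyond the
surrogate's propensity structure. Passing tests therefore demonstrate
that the pipeline's logic and statistics behave as designed on a cohort
with the stated geometry statistics — not that the risk model transfers
to patient data.

## Classification harness

Features per (model, segment): segment myocardial volume, segment
ischemic %, total myocardial volume, total ischemic volume; element-sum
volumes, no smoothing. Classifiers and fixed hyperparameters: kNN (k=5),
SVC (RBF, C=2, probability outputs), logistic regression, decision tree
(max depth 3), gradient-boosted trees (pinned defaults: 100 estimators,
depth 6, η=0.3, hist method), and 3-/4-hidden-layer MLPs (32-17-8 and
32-17-8-8 ReLU units, SGD with zero momentum, constant learning rate
0.01 — the emulated exponential decay of 0.9 per 10⁵ steps is negligible
over 25 epochs — batch size 20, 25 epochs). The MLPs are scikit-learn
`MLPClassifier` networks; they have no batch normalization, which is why
the separable-fixture test uses enough rows for the deep narrow net to
converge within its epoch budget.

Splits are 70/30 by row (floor(0.7·n) train), repeated (100 runs
default; smaller counts in tests to fit time budgets) with seeds derived
from a root seed. The default standardization mode standardizes each
split with its own mean/SD — leakage-free but unconventional, kept as
the faithful default — with a conventional train-fit mode available.
Zero-variance features are centred only, with a warning. Metrics:
accuracy/precision/sensitivity at threshold 0.5 from explicit confusion
counts, average precision and trapezoidal ROC AUC (scikit-learn); the
test suite proves both against brute-force enumeration and
Mann–Whitney pair counting. Arms are compared per model with a one-sided
Welch t-test (augmented mean greater) and a one-sided F-test (augmented
variance smaller); the two-sided t p-value is reported alongside since
the sidedness is a modelling choice. No class rebalancing is applied
(positive rates ≈0.13–0.22); stratification is available as an option.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small instances: CV
checks on a 60×10 strand at 0.25 mm; mesh convergence on 0.125 vs
0.0625 mm strands; restitution with 19 drive beats and a 27-point DI
grid; population studies with 10–30 patients on 120×120 sheets at
0.25 mm; classifier experiments with 15–25 runs per arm. The directional
augmentation and monotone-trend checks aggregate over ten independent
population seeds, so they test the structural claim rather than one
lucky draw.

## Known limitations

- The surrogate backend reproduces the cohort-level structure of
  protocol outcomes but is not an electrophysiological model; full
  monodomain protocol runs are possible through the tissue backend but
  are only practical on coarse fixtures at single-CPU scale.
- Reentrant wavelengths at physiological conductivities (~12 cm) exceed
  the desk-scale sheets. The reentry-capability demonstration therefore
  runs at reduced conductivities (σ_l = 0.0272, σ_t = 0.0075 S/m — a
  standard fixture-scale device, not a physiological regime), uses a
  graded disc whose core has full KATP activation (severe acute
  ischemia, inexcitable — it anchors the circuit like the unexcited
  infarct cores seen in patient-model activation maps), shortens the
  action potential with a fast S1 drive through the steep preset's own
  restitution, and delivers the premature S2 from a 3 mm electrode at
  the disc's rim: the S2 blocks unidirectionally into still-refractory
  tissue and the wave circulates around the disc, re-exciting tissue
  behind it. Two numerical pitfalls found while building this fixture
  are worth recording: strong global KATP activation raises the capture
  threshold enough to block propagation on coarse grids, and transverse
  conductivity reduced much below ~0.007 S/m at 0.25 mm spacing falls
  under the discrete propagation limit (wavefronts stall on the
  cross-fiber flanks).
- 2D slabs have no transmural dimension; the AHA tiling on slabs is a
  bookkeeping substitute, not an anatomical mapping.
- Scar evolution over time, fibrosis texture, and image-derived infarct
  shapes are out of scope.
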