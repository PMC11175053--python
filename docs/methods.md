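# Methods

## The problem

Collar-worn inertial sensors make it cheap to *record* animal behavior and
expensive to *label* it.  This package implements a semi-supervised training
method — cleaned meta pseudo labels (CMPL) — for classifying 2-s windows of
12-channel sensor data (gyroscope, accelerometer, magnetometer x/y/z and
rotation roll/pitch/yaw, sampled at 50 Hz) into five dog behaviors: stand,
walk, sit, lying, eat.  Two practical obstacles shape the method:

1. most windows are unlabeled, so a teacher–student pseudo-labeling scheme
   must extract signal from them; and
2. the unlabeled pool is contaminated with *inactive* windows — idle
   segments belonging to no behavior class — which poison naive
   pseudo-labeling and must be detected and quarantined during training.

## The training loop

Each step draws a labeled and an unlabeled sub-batch (equal size, sampled
with replacement) and proceeds:

1. **Pseudo-labeling.** The teacher predicts class probabilities for the raw
   unlabeled windows; the argmax over the six classes (five behaviors plus
   the dedicated inactive class, index 5) is the hard pseudo label ŷ_u.
   Ties break to the lowest index.
2. **Cleaning.** Each unlabeled window gets a distance score
   S(x) = ‖φ(x) − C‖², the squared Euclidean distance of its feature vector
   from the running centroid C of labeled features.  Windows with
   S > T = μ + β σ (strict) are flagged as inactive.  In the default
   `relabel` mode their pseudo label is rewritten to class 5; in `exclude`
   mode they get zero weight in the student loss.
3. **Student update.** One SGD step on the cross entropy between the
   cleaned pseudo labels and the student's predictions on the raw unlabeled
   windows.
4. **Teacher feedback.** h = CE_labeled(student before) − CE_labeled(student
   after): positive when the pseudo labels made the student better on
   labeled data.  The teacher's MPL term is h · CE(ŷ_u, teacher logits).
   With this sign convention the expectation of the MPL gradient over the
   teacher's pseudo-label distribution equals the exact gradient of the
   two-step bilevel objective E_ŷ[CE_labeled(θ_S − η_S ∇CE(ŷ, θ_S))] — the
   package's bilevel test verifies this against closed-form finite
   differences on an enumerable toy problem.  (With the opposite sign, the
   teacher would be pushed *away* from pseudo labels that helped.)
5. **UDA consistency.** The teacher also minimizes supervised CE on the
   labeled batch plus a consistency term: cross entropy between its own
   (detached) predictions on a weakly augmented view and its predictions on
   a strongly augmented view of the same unlabeled windows.
6. **Distance loss.** Mean squared distance of the labeled batch's features
   from C, compressing the labeled embedding around the centroid (C is a
   constant within the step).  The term enters the teacher loss with weight
   `dis_weight` (default 0.05), the usual center-loss convention: at full
   weight the compression overpowers the supervised signal whenever the
   labeled pool is small, collapsing the classifier before it forms.
7. **Teacher step.** One SGD step on L_MPL + L_UDA + dis_weight · L_dis.
8. **Detector updates.** C takes an exponential step toward the labeled
   batch's feature mean (rate η_C); μ and σ are exponential moving averages
   (rate α) of the labeled batch's score mean and standard deviation;
   T = μ + β_t σ with β_t ramped linearly by the scheduler.

Cleaning is inert (T = +∞) for a warm-up period (default 10% of steps) so
the embedding can form first.

### Relabeling feedback and its safety gate

Flagging alone turned out not to be a stable detector: a window flagged at
step t but not trained as "inactive" is still optimized *toward its pseudo
behavior class* by the MPL and consistency terms, so the embedding gradually
re-absorbs true inactive windows and final-threshold recall collapses.  The
relabeling therefore extends to the teacher's consistency target: a flagged
window's target distribution becomes one-hot on class 5, which teaches the
teacher to place it away from the behavior clusters and keeps it flagged.

That feedback is self-reinforcing, so a *false* flag could lock itself in.
The relabeling is therefore vetoed by the teacher's own class posterior: a
flagged window whose maximum behavior probability is ≥ `rewrite_conf_gate`
(default 0.95) keeps its behavior pseudo label and ordinary consistency
target — the distance rule proposed the flag, and the classifier
confidently overruled it.  Empirically the two populations are far apart
(active windows are classified at ≈0.98+ confidence once training has
progressed; inactive windows rarely exceed 0.8), so the veto prunes false
flags at almost no cost in recall.  The final detector reported by
`detect_inactive` remains the pure distance rule S > T.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `batch_size` | 50 (desk preset 16) | windows per labeled and per unlabeled sub-batch |
| `total_steps` | 50,000 (desk preset 2,000) | training iterations |
| `student_lr`, `teacher_lr` | 0.03 | constant SGD rates |
| `centroid_lr` η_C | 0.1 | exponential step of C toward the batch feature mean |
| `ema_alpha` α | 0.05 | EMA rate for μ and σ |
| `beta_start` → `beta_end` | 1.0 → 3.0 | linear ramp of the threshold coefficient β |
| `warmup_frac` | 0.1 | fraction of steps with cleaning inert |
| `noise_mode` | `relabel` | `relabel` → class 5; `exclude` → zero student weight |
| `dis_weight` | 0.05 | weight of L_dis in the teacher loss (center-loss convention) |
| `clip_norm` | 5.0 | global gradient-norm clip (both models); `None` disables |
| `rewrite_conf_gate` | 0.95 | veto the class-5 relabel for confidently-classified windows |
| `eval_ema` | 0.99 | Polyak decay of the parameter copies used for test metrics |
| `jitter_sd` | 0.05 | weak-augmentation noise, normalized units |
| `flip_probability` | 0.0 | weak-augmentation sign flip (see below) |

Design notes on the less obvious choices:

* **β schedule.** β must place T between the labeled score distribution and
  the contaminant tail.  Starting at β = 1 keeps the bootstrap conservative
  (a cut inside the labeled distribution would flag ordinary windows, and
  the relabeling feedback would entrench the mistake); ending at β = 3
  follows the observation that σ shrinks as the embedding compresses, so the
  cut tightens in absolute terms while loosening in σ units.
* **Sign flip off by default.** The synthetic classes are distinguished
  partly by *signed* posture baselines (lying vs sit differ in the sign
  pattern of magnetometer/rotation offsets), so a global sign flip is not
  label-preserving on these data and would corrupt the consistency target.
  The operation is implemented and available for data where mirroring is a
  true invariance.
* **Pseudo labels from the raw view.** The teacher labels the plain
  unlabeled window; the weak view serves only as the consistency target.
  Labeling an augmented view would let augmentation noise leak into the
  student's targets.
* **Gradient clipping.** The combined teacher loss has a large transient at
  the start (the distance loss before any compression); plain SGD needs the
  global-norm clip to survive it.  The clip rarely binds after the first
  dozen steps.
* **Polyak evaluation copies.** With a constant learning rate the SGD
  iterates keep oscillating; reading test metrics off a 0.99-decay average
  removes ±10-point endpoint noise without touching the training dynamics.
* **Optimizer.** Plain SGD matches the printed update rules; momentum is
  available behind a flag but off by default.

## The synthetic data generator

The recordings the method was designed for are not public, so the package
ships a generator that emulates their statistical structure:

* Each behavior class is a **harmonic motion motif**: per-sensor amplitudes,
  a fundamental frequency with 1/k-weighted harmonics, white sensor noise
  (sd 0.15), and a 12-channel posture baseline (lying and sit differ mainly
  in magnetometer/rotation offsets; eat is acc-dominated at 4.5 Hz; walk is
  strong periodic gyro/acc at 2.5 Hz; stand is low-amplitude 0.3 Hz drift).
* The **inter-channel phase pattern is a fixed property of each class**
  (repetitive behaviors keep their limb/head coordination), with a
  per-window phase wobble of 0.4 rad.  Fully independent phases would make
  windows of one class mutually distant in raw space — the nearest raw-space
  neighbor of any high-energy window would be a *low*-energy class — and no
  instance-based learner could work.
* **Inactive windows** are static postures plus low white noise (sd 0.05).
  The dataset builder centers each one near the baseline of a randomly
  chosen behavior class (per-channel deviation 0.2) — an idle animal rests
  in realistic postures, not at exotic sensor readings — so what
  distinguishes inactive data is the *absence of motion*, not position.
  This also makes the contamination genuinely harmful to naive
  pseudo-labeling: an inactive window resting in a lying-like posture that
  gets pseudo-labeled "lying" corrupts that class's boundary, which is the
  failure mode the cleaning stage exists to prevent.  Standalone inactive
  windows (no posture supplied) draw a free offset with sd 0.6, comparable
  to the baseline spread.
* **Missing values** mimic Bluetooth dropouts: a window is hit with
  probability `missing_rate`; the gap is contiguous, covers all 12 channels,
  and has geometric length with mean 5 samples.  Preprocessing deletes
  affected windows outright — no interpolation.

What the generator does **not** emulate: real gait nonstationarity,
transitions between behaviors inside a window, sensor drift and
miscalibration, inter-individual variation, or class imbalance.  Passing
tests on these data show the training machinery behaves as specified — they
do not certify field accuracy on real dogs.

## Desk-scale study conditions

All shipped experiments run on one CPU core:

* **Detection study** (also the default of `examples/03_train_cmpl.py`):
  40 labeled windows/class, 300 unlabeled with 30% inactive and 5% missing,
  batch 16, 2,000 steps (≈1 min/run).  Detection is scored as
  precision/recall of the final flagged set against the generator's mask.
* **Method-ordering benchmark** (`examples/04_benchmark.py`): harder motif
  variant (noise sd 0.25, phase wobble 1.2 rad) and a 100/class base pool
  subsampled to 20% labels (20/class kept), so the supervised baseline is
  off its ceiling; supervised and MPL+UDA run 800 steps, cleaned runs 2,000
  with a 40% warm-up (the detector needs a mature classifier before its β
  ramp).  The embedding-distance detector needs the labeled subset to
  *cover* the class manifolds: with very few labeled windows (≲10/class)
  the distance statistics reflect memorization, unseen active windows score
  as outliers, and cleaning turns harmful.  The benchmark conditions keep
  the method inside its operating regime, which is also the regime of the
  original experiments (cleaning was only ever run with the full labeled
  pool there).

## Numerical choices

* All math is float64 numpy; runs are bit-reproducible given the config
  seed, and every stochastic component (generator, batch sampler,
  augmentations, init) derives from `numpy.random.default_rng` seeds.
* The networks run on a small reverse-mode autodiff core written in the
  package (`cmpl._autodiff`); gradients of every composite operation are
  finite-difference-tested.
* Zero-variance channels get their normalization sd clamped to 1e-8.
* S > T is a strict inequality; argmax ties break to the lowest class index.
* The centroid, μ and σ initialize from the first labeled batch of the run.
* Confusion matrices are row-normalized over the five behavior columns;
  predictions of the inactive class on behavior-labeled test data count as
  errors in accuracy/F1 and leave their row's mass reduced before
  normalization.

## Known limitations

* The inactive-data detector requires labeled coverage; see above.  A
  production system facing very small labeled pools should prefer
  `mpl+uda` (cleaning off) or collect more labels before enabling cleaning.
* Class-5 logits exist even when cleaning is disabled; the class is simply
  never assigned.
* The full-scale protocol (batch 50, 50,000 steps) is supported but not
  exercised by the shipped experiments; desk-scale presets are the tested
  path.
* The larger backbone presets (`resnet18-like` and up) share the block
  structure of `small` at greater width/depth; they are provided for layout
  parity, not as faithful parameter-count reproductions of the named
  architectures.
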