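# Methods

## The model

Semi-supervised self-training with hard pseudo-labels. A classifier
`f_θ` with a softmax head is trained on the labelled pool; for each
unlabelled sample the prediction `ŷ = argmax f_θ(x)` is promoted to a
training label iff its confidence `max f_θ(x)` meets a threshold τ
(inclusive: `≥ τ`, with argmax ties broken toward the lowest class index).
The training objective over the merged set is

    L_total = L_sup + λ_eff · L_unsup,

both terms mean categorical cross-entropy (natural log; the probability of
the true class clamped at 1e-12), with `λ_eff = λ·min(1, epoch/ramp)` under
an optional linear ramp and `L_unsup = 0` for an empty pseudo-label set.
In the pipeline λ is realised as a per-sample weight on pseudo-labelled
rows of the merged set (`Σ w·ce / Σ w`), which reduces to plain merged-set
cross-entropy at λ = 1.

**Iterative rejection.** Iteration *t* scores the *currently remaining*
pool on clean (normalisation-only) images at threshold `τ_t` from a
non-increasing schedule (default 0.98, 0.95, 0.90); accepted samples merge
into the training set and the model retrains (warm start by default, a
from-scratch flag exists); rejected samples carry to iteration *t+1*; the
loop stops when the schedule is exhausted or the pool empties, and samples
still rejected at the end are permanently excluded. The ledger records
(iteration, threshold, accepted, rejected) with the invariant
`accepted_t + rejected_t = pool_t` and `pool_{t+1} = rejected_t`.

**Two-model consensus.** With a grayscale and an RGB branch, a pseudo-label
is accepted only when the two argmax classes agree and the combined
confidence (max of the two; mean available) meets τ. Disagreement rejects
the sample by default — with two voters, "majority" is unanimity, and
rejection favours label purity; a `max_confidence` fallback is provided.
The final classifier in consensus mode is a fusion head (dropout 0.5 →
dense 256 ReLU → dropout 0.3 → softmax, Adam 1e-4) over the concatenated
branch feature vectors (128 + 512 = 640 for the full-size pair). The head
trains on frozen branch features; the branches themselves are refreshed
once on the merged set before fusion (flag-controlled).

## Architectures and optimisation

The networks are built on a small in-package numpy engine (`pseudofuse.nn`)
— valid-padding convolution, non-overlapping max pooling, global average
pooling, dense/ReLU/inverted-dropout layers, explicit backprop, Adam and
Adamax — chosen for bit-reproducible single-threaded training at the
problem sizes this package targets.

* **Custom grayscale branch** (168×168×1): conv(64, 5×5) → pool(3×3) →
  conv(64, 5×5) → pool → conv(128, 4×4) → pool → conv(128, 4×4) → pool →
  flatten → dense(512, ReLU) → softmax. All four pools are 3×3: that choice
  reproduces the reference feature-map ladder 164→54, 50→16, 13→4, 1×1×128
  exactly (a pool window larger than the map is skipped). Features are the
  dense-512 activations. Adam with η = 0.001, β1 = 0.85, β2 = 0.9925.
* **Transfer branch** (224×224×3): any backbone mapping images to a 4-D
  feature map (the desk default is a small randomly-initialised 3-block
  CNN; a pretrained network can be plugged in when available offline),
  then GAP → dropout 0.5 → dense(128, ReLU) → dropout 0.5 → softmax;
  Adamax, η = 1e-4; backbone frozen by default.
* **Tiny variants** (≥32×32) keep the same contracts with two conv blocks
  (8/16 filters) and dense-32 features; they are the test and benchmark
  workhorses.

Training details: batch training with per-epoch shuffling from a seeded
generator; optional best-checkpoint restore on validation accuracy (the
validation set is a stratified 10% carve-out of the labelled pool, since
the protocol defines none); the "reduce LR on multiple accuracies" callback
multiplies the learning rate by 0.75 the first time validation accuracy
exceeds each of 0.96 / 0.99 / 0.9935, floored at 1e-4. Dropout acts only
during fitting; inference is deterministic.

**Preprocessing** (training): random horizontal flip (p = 0.5), rotation
uniform in ±2% of a full turn (±7.2°), zoom and translation within ±5%,
contrast scale within ±10% about the image mean — bilinear interpolation
with reflect padding — followed by division by 255. Evaluation applies
normalisation only. `normalize` rejects input already in [0, 1], making
double normalisation a loud error. The 2%-rotation reading (fraction of a
turn) follows common augmentation-layer semantics; zoom/translation
magnitudes are unstated upstream and default to a conservative 5%.

## Synthetic data

`generate_phantoms` renders four classes over a smooth elliptical "brain"
background: (0) an eccentric bright ellipse with a ragged, harmonically
perturbed edge; (1) a bright ring; (2) a small bright disc in the lower
half; (3) background only. Classes 0 and 1 are the designed hardest pair
(filled ragged mass vs. thick ring). Per sample: pose jitter (±18%
translation, ±18° rotation, ±25% size), a background grey level drawn from
N(80, 12²), a lesion level at a random fraction (0.55–1.0) of the
difficulty-scaled contrast, and Gaussian pixel noise (default sd 10 on the
8-bit scale); `difficulty` ∈ [0, 1] both scales lesion contrast as
(1−difficulty)² and shrinks the ring's hole toward a filled mass. Values
are clipped to [0, 255]; generation is byte-deterministic per config.

The per-sample intensity variability is essential: without it a global
grey-level statistic separates the classes and a tiny CNN saturates from 20
labelled images, leaving self-training nothing to recover. With it,
supervised accuracy degrades as the labelled fraction shrinks (≈85% at full
labels vs. ≈60–75% at 10% labels for the tiny CNN), which is the regime the
method addresses.

What the phantoms do **not** emulate: anatomy, scanner intensity
nonuniformity, inter-patient variability, class imbalance, 3-D structure.
A passing benchmark therefore shows the *mechanism* works end-to-end
(confident, mostly-correct pseudo-labels improve a data-starved
classifier); it says nothing about absolute accuracy on real MRI.

## The benchmark protocol

`phantom_benchmark`: per seed, a fresh 200-image training pool (50/class,
32 px — the tiny CNN's minimum input, chosen to keep ten paired runs in
minutes) and a 200-image test set; stratified 10% labelled split; the
supervised baseline trains 50 epochs (batch 8, sized to the 20-image
labelled pool); the SSL arm starts from the identical warm-up and runs the
iterative loop with full 50-epoch retraining after each expansion;
augmentation on in both arms; no validation carve-out (2 images would make
checkpointing noise). Reported per seed: both test accuracies, their
paired difference, accepted/rejected totals, and pseudo-label precision
against the hidden truth.

Known confound, inherited from the protocol this mirrors: the SSL arm
receives more total gradient steps than the fixed-budget baseline, so part
of the gain can come from longer training whenever pseudo-labels are
plentiful and clean.

## Statistics conventions

* Paired *t*-test: `t = d̄/(s_d/√n)`, sample SD (n−1), one-tailed upper
  p from Student's t with df = n−1; zero-variance input reports a boundary
  p (0/0.5/1 by the sign of d̄) with a warning. Descriptive Mean ± SD
  summaries use the population SD (÷n), matching the convention of the
  published tables shipped as inputs.
* Binomial CI: normal approximation `p ± z√(p(1−p)/n)`, z = 1.96, bounds
  on the percent scale and deliberately unclipped.
* Cohen's d: pooled SD `√(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2))`; at equal n
  this is `√((s₁²+s₂²)/2)` and the group size cancels.
* McNemar: `χ² = (max(|b−c|−1, 0))²/(b+c)` (Yates correction, clamped so
  b = c gives 0 rather than a positive statistic), two-sided p from χ²₁;
  requires b + c > 0.
* Cohen's κ on the 2×2 correct/incorrect table: `(p_o − p_e)/(1 − p_e)`
  from the marginals, `None` when p_e = 1. Note that when both classifiers
  are near ceiling, p_e ≈ p_o and κ is necessarily tiny even at 96%+
  agreement — κ on the 2×2 outcome table answers a different question than
  κ on a C×C label-agreement table.
* Percentile bootstrap: resample the correctness flags with replacement to
  the original size B = 1000 times; report median, 2.5/97.5 percentiles,
  and SE with the 1/(B−1) variance convention; seeded and deterministic.

The shipped reference tables are treated strictly as inputs; the suite
reports whatever the formulas give on them. Two published summaries are not
recoverable from their own tables by the standard formulas (the t statistics
implied by the accuracy columns are ≈4.72/≈2.25, and the 2×2 κ is ≈0.027);
the recomputed values are asserted in tests rather than the published ones.

## Numerical and design choices

* Class indices are 0-based internally; alphabetical name order at I/O
  boundaries unless an explicit ordering is supplied.
* Stratified splits use the largest-remainder rule (total = round(f·n),
  per-class floors, leftovers by largest fractional part, ties by index).
* Probability-matrix rows must sum to 1 within 1e-6; violations raise.
* Confidence of an agreed consensus label defaults to the max of the two
  model confidences (mean available); both are documented conventions.
* The iterative loop treats a scoring function and a retrain hook as its
  interface, so a scripted model with frozen confidences can drive it in
  tests; a hook failure re-raises with the partial ledger attached.
* Single root seed per run, fanned out deterministically (split, init,
  shuffling, dropout, augmentation draws, bootstrap) — one integer
  reproduces a run bit-for-bit on one thread.

## Limitations

* The numpy engine is educational-scale: no GPU, no threading; full-size
  (168/224 px) networks are practical for forward passes and structural
  checks, while training at scale is the tiny variants' job.
* Soft pseudo-labels, temperature scaling, consistency regularisation and
  entropy minimisation are out of scope by design.
* The transfer branch's default backbone is randomly initialised; with
  dropout 0.5 over its 32 pooled features the head is a deliberately slow
  learner, and desk-scale runs use a larger learning rate than the
  full-size default.
* κ = on the paired 2×2 table (see above) is near zero at ceiling accuracy;
  interpreting it as inter-model agreement strength requires the full C×C
  table, which the 2×2 schema cannot carry.
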