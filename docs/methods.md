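# Methods

## The model

`cinet` studies how flanking context changes the classification of a
degraded or ambiguous visual stimulus. A target bitmap `T` at position
`j` is flanked by `S1` context bitmaps on the left and `S2` on the right
(span `S = S1 + S2`). Each slot `i ∈ {-S1, …, S2}` carries a coupling
weight `α_i ∈ [0, 1]` and additive zero-mean Gaussian pixel noise with
its own variance; slot content is

    R_{j+i} = α_{j+i} · C_{j+i} + N_{j+i}        (target slice: i = 0)

with the noise added *after* weighting, so attenuating a context letter
does not attenuate its noise. The weighted, noisy slots are depth-stacked
into an `H × W × Z(1+S)` cuboid (`Z = 1` for binary letters). With
`S1 = S2 = 0` this degrades gracefully to an ordinary context-free
classifier whose input is the bare target.

The classifier is a small CNN whose first-layer filters span the full
z-depth of the cuboid, so every receptive field couples target and
context pixels; this is the mechanism by which context enters the
decision. The standard architecture (used in all experiments, built by
`NetworkSpec.cinet(span)`) is:

    32×32×(1+S) → conv 32@3×3 (valid) → 30×30×32
                → conv 32@3×3 (valid) → 28×28×32
                → maxpool 2×2 stride 2 → 14×14×32 → flatten 6272
                → dense 100 (sigmoid) → dense 6 (softmax)

Softmax outputs are read as class posteriors `p(ω_i)` and the decision is
`ω* = argmax_i p(ω_i)` with ties broken toward the lowest class index.
Training minimises cross-entropy by mini-batch gradient-descent
backpropagation and stops when the *full-training-set* mean cross-entropy
falls below 0.001 (an epoch-mean reading of the stop rule; a per-sample
or per-batch reading would stop slightly earlier or later but at these
loss levels the trained networks classify their training set perfectly
either way).

Two forward-pass implementations exist on purpose. `cinet.network` is the
vectorised one (im2col + BLAS matmuls, float32 by default).
`cinet.reference` transcribes the layer equations as scalar Python loops
(triple sum over `(z, u, v)` per output cell, explicit window maxima,
explicit weighted sums). The test suite holds the two to agree within
1e-5 on random architectures; the reference is never used for anything
else.

## Stimuli

All stimuli are committed fixtures (`src/cinet/data/glyphs.txt`): 26
hand-designed 32×32 block letters (stroke width 4 px, authored on a 16×16
grid and upscaled ×2) plus three ambiguous hybrids. Six letters —
A, H, O, U, P, R — are the target classes. Each hybrid is built from one
parent's skeleton plus exactly half of the pixels that distinguish the
other parent (e.g. [A/H] is the H frame plus the central half of A's top
bar), which makes it Hamming-equidistant from both parents by
construction and strictly farther from the other four targets (verified
in the test suite). Ambiguity/degradation is introduced by adding i.i.d.
zero-mean Gaussian noise to every pixel, foreground and background,
leaving values unclipped so the empirical variance matches the nominal
σ² exactly.

What the generator deliberately does *not* emulate: font rasterisation,
stroke-level distortions (added/deleted/skewed segments), blur or
resolution changes, and any irregularity of real letterforms. The
fixtures are maximally clean: strokes are thick, classes are far apart
(minimum pairwise Hamming distance 48 of 1024 pixels among targets), and
hybrids are exactly ambiguous. A green trend test therefore establishes
that the *mechanisms* (context integration, noise degradation,
incongruence costs) behave correctly — not that the absolute
probabilities match what thinner, messier letterforms would produce; see
"Known limitations".

## Experiments

Three classifier pools are trained per run: CINET(0) on isolated target
letters, CINET(2) on {BAG, THE, MOW, FUN, SPY, IRK} and CINET(4) on
{BEAST, ETHYL, FLUID, GNOME, IMPLY, SCREW}, always with unity weights and
σ² = 0.001 noise on target *and* context exemplars ("noise-free"
training). Seven table rows are then evaluated per center type
(ambiguous hybrid vs plain target letter): context-free (Set 1),
congruent noise-free context at spans 2 and 4 (Sets 2–3), attenuated
weights 0.7 uniform and 0.4/0.7 decaying (Sets 4A/4B), context noise
matched to center noise (Set 5), and left/right-exchanged context
(Set 6). Congruent test context is exactly noise-free (variance 0, not
0.001). Sets 4A, 4B and 5 reuse the Set-3 pool; Set 6 reuses the Set-2
pool.

Scoring: with context, a trial is correct iff the decision equals the
class implied by the surrounding word (for B[A/H]G only A counts);
without context, an ambiguous trial is correct iff the decision is either
parent (two of six classes), and a plain-letter trial iff it is the true
class. Each table entry is a two-stage average: mean over
networks × samples per test item, then mean over the items. Each
ambiguous letter appears in two words; the per-(letter, word) means are
exposed via `ExperimentResult.per_item()` so either pooling can be
inspected.

## Replication scale

The published protocol is 30 networks × 100 samples per item. The default
desk-scale profile (`CI_PROFILE`) is 5 networks × 50 samples and 30
training exemplars per class, chosen purely for single-CPU runtime; the
full profile (`FULL_PROFILE`, `--profile full`) restores 30 × 100 and 100
exemplars per class. At σ² = 0.001 the exemplars are near-duplicates, so
the smaller training set does not change what is learned; the smaller
test count only widens Monte-Carlo error (binomial SE ≈ 0.013 at p = 0.5
with 1500 trials per entry), which is why table comparisons in the tests
carry explicit 2-SE slack.

## Numerical choices

- **Optimizer.** Plain SGD at small learning rates does not reach the
  0.001 cross-entropy stop in a reasonable epoch budget (the threshold
  demands mean true-class posteriors ≈ 0.999). The default is mini-batch
  SGD with momentum 0.9, learning rate 0.1 and batch 16 (Adam is
  available but has a slower tail here), with two safety nets:
  reduce-on-plateau halving of the rate while the loss is still far from
  the stop (oscillating runs settle once the rate drops), and
  deterministic re-initialisation (up to 4 restarts) of runs that settle
  into a poor local minimum — the context-free pool occasionally lands in
  an 83%-accuracy basin from which no learning rate recovers. Word-pool
  networks converge in ~6–15 epochs, context-free ones in ~30–300;
  learning rate 0.2 destabilises the context-free pool. The exact
  full-set loss (the stopping quantity) is evaluated once the epoch-mean
  batch loss comes within 5x of the stop; earlier epochs log the epoch
  mean. Divergence (non-finite loss or weights) raises an error naming
  the learning rate.
- **Initialisation.** Glorot-uniform weights, zero biases, one seed per
  network.
- **Determinism.** Every random stream derives from the run's global seed
  via CRC-tagged `SeedSequence`s (`derive_seed`), so a run is exactly
  reproducible and sub-seeds stay below 2³¹.
- **Precision.** Networks train and evaluate in float32; the reference
  path and the oracle-equivalence tests use float64.
- **Tie-breaks.** Argmax ties (decision rule and pooling backprop
  routing) resolve to the first/lowest index.
- **Degenerate inputs.** Zero-variance noise is an exact identity;
  pooling rejects non-integral output dimensions; context counts,
  z-depths and bias/filter counts are validated eagerly.
- **Non-convergent networks** (final loss > 10× the stop threshold) are
  excluded from evaluation with a warning and recorded in the result
  manifest. In practice all pools converge.

## Known limitations

- With congruent context the surrounding word *uniquely identifies* the
  class, and networks trained on near-noise-free words exploit this:
  probing shows the context slices alone essentially determine the
  decision. With the clean committed fixtures this saturates Sets 2–5
  near probability 1.0 across the whole noise sweep, and under flipped
  context (Set 6) decisions scatter roughly uniformly over all six
  classes (≈ 1/6) rather than concentrating on the two parents. Reported
  context-effect magnitudes are therefore upper bounds tied to this
  stimulus world; letterforms with thinner strokes and smaller
  between-class separation would degrade faster and lean more on the
  center stimulus.
- The context-free baseline for ambiguous letters is likewise
  fixture-dependent: exactly-equidistant hybrids whose nearest targets
  are their parents are almost always classified into a parent class even
  under heavy noise (2-of-6 scoring), so the ambiguous Set-1 row can sit
  *above* its plain-letter counterpart at high noise, where only 1 of 6
  classes counts.
- Only the stacking integration mode is implemented (averaging and
  concatenation are not), experiments are 2-D (`Z = 1`) although the data
  model accepts `Z ≥ 1`, and the architecture family is
  conv–conv–pool–FCN; GPU execution and data augmentation beyond the
  stated noise are out of scope.
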