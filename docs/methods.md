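# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `mscascade`, in the order data flows through the package.

## Signal conditioning (`io_core`)

Recordings are channel × sample matrices in microvolts with an ordered
10–20 montage (19 channels by default; the bundled plain-text table
carries 2D projected electrode positions). The conditioning chain is:

1. **Average re-reference.** Every microstate quantity below assumes the
   spatial mean is zero at each sample: global field power (GFP) is the
   spatial standard deviation, and spatial correlations are computed on
   mean-removed maps. Re-referencing is idempotent and preserves GFP
   exactly. It is applied before all microstate computation even when
   the source data is mastoid-referenced.
2. **Band-pass filtering.** Zero-phase (forward–backward) Butterworth,
   order 4 per pass. The band grid: broadband 0.5–45, delta 0.5–4,
   theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz. Order 4 is the
   conventional EEG choice; the filter family is fixed, the order is a
   parameter.
3. **Resampling** to 256 Hz by polyphase filtering with anti-alias
   low-pass (`scipy.signal.resample_poly`); output length is defined as
   round(n · target/rate) and enforced by trimming/edge-padding at most
   one sample. Upsampling is permitted but logged.
4. **Epoching.** 10 s windows with a 5 s step. A window starting at
   k·S is kept only while k·S + W is *strictly* less than the recording
   length — the window ending exactly at the boundary is dropped. This
   convention yields 58 epochs for a 300 s recording at 256 Hz (the
   inclusive convention would give 59) and therefore 5104 epochs for an
   88-subject cohort. Sample indices are 0-based; epoch k covers the
   half-open interval [k·S, k·S + W).

## Microstate extraction (`microstate`)

**GFP peaks.** Template candidates are topographies at strict local
maxima of the GFP series (endpoints excluded) — the moments of highest
topographic signal-to-noise.

**Polarity invariance.** Oscillation phase flips a topography's sign
without changing the underlying generator configuration, so all
similarities are absolute Pearson correlations across channels of
mean-removed maps. A signed mode exists behind a flag for the soft
sequences.

**Modified k-means.** Peak maps are assigned to the template with the
highest |ρ|; each template is re-estimated as the dominant eigenvector
of the outer-product sum of its assigned maps (the polarity-proof
analogue of the cluster mean — a signed mean would cancel under random
sign flips). Defaults: K = 4, 20 random restarts (initialized from
observed maps), convergence when assignments stabilize or the global
explained variance (GEV) improves by less than 1e−6, 100 iterations
maximum; the restart with the highest GEV wins. Dead clusters are
reseeded on the worst-fitted map. GEV is the GFP-weighted squared
correlation fraction, GEV = Σ_t (GFP_t·ρ_best(t))² / Σ_t GFP_t².

**Canonical labels and cross-band alignment.** Independent clustering
gives permuted, unlabeled templates. Broadband templates receive their
A–D letters by minimum-cost bipartite matching (cost 1 − |ρ|, Hungarian
algorithm) against built-in dipolar prototypes for the bundled montage:
A right-anterior/left-posterior diagonal, B the mirrored diagonal, C an
anterior–posterior midline gradient, D a focal posterior/parietal
distribution. Each narrowband set is then Hungarian-matched to the
broadband anchor with the same cost, so class letters keep one meaning
across bands. The canonical-letter assignment mechanism is this
package's choice; only the cross-band anchoring is inherent to the
method. Hungarian solutions are verified against exhaustive 4!
enumeration in the tests.

**Soft backfitting and fusion.** Rather than winner-takes-all labels,
each epoch yields r_k(t) = |ρ(x(t), m_k)| for the four aligned
templates — a (4, 2560) trajectory in [0, 1]. Zero-variance frames have
undefined correlation; they are emitted as 0 and their indices flagged.
Stage inputs fuse two bands row-wise into (8, 2560): rows 0–3 the first
band's classes A–D, rows 4–7 the second band's. Stage 1 (screening)
fuses alpha + delta; stage 2 (subtyping) fuses delta + theta.

**Descriptive statistics.** For the classical feature baselines the
soft sequence is discretized by per-sample argmax and merged into
segments. Coverage is the sample share, occurrence the segments per
second, mean dwell the mean segment duration in ms. Transition
probabilities are row-normalized counts between consecutive *distinct*
segments — P(next = k | current = j, a transition occurs) — so any row
with at least one observed transition sums to 1; states with no exit
get an all-zero row and are flagged rather than raising.

## The classifier (`nn`)

A 1D convolutional network with no normalization layers anywhere,
implemented in NumPy with hand-written backpropagation (float32):

    stem conv (kernel 15, stride 2) → ReLU
    → NF-ResBlocks: out = relu(proj_1x1(x) + conv_7(relu(conv_7(x))))
    → max-pool (stride 4)
    → multi-head self-attention (4 heads, embedding 64)
    → global average pooling → dropout 0.5 → linear logits

A 2560-sample epoch maps to 320 attention tokens (2560/2/4). The
residual blocks are plain convolutions with 1×1 projection shortcuts —
no weight standardization or scaled residuals; stability is delegated
entirely to adaptive gradient clipping. The MHSA module projects
channels tokenwise to the embedding with no positional encoding (the
convolutional stem already encodes local order; adding one is left as
an extension). Head-averaged, query-averaged attention provides one
non-negative distribution over the 320 tokens per epoch (sums to 1),
with a nearest-neighbour upsampling to the 2560-sample axis for
overlays.

Default widths are stem 32 and blocks (32, 64, 64); the desk-scale
configuration used by the tests and the acceptance benchmark narrows
this to stem 8, blocks (8, 16), embedding 16 — the depth, kernel sizes,
strides and attention heads are unchanged.

**Adaptive gradient clipping.** For each unit i (a row of a weight
matrix / an output channel of a convolution; single elements for 1D
parameters), if ‖G_i‖_F / max(‖W_i‖_F, ε) > λ the gradient is rescaled
to norm λ·max(‖W_i‖_F, ε), else left alone; λ = 0.04, ε = 1e−3 (the ε
floor lets zero-initialized units escape: a unit-norm gradient on a
zero weight is clipped to 4e−5, not 0). Clipping never increases a
unit's norm and preserves direction. AGC is applied to every parameter
including the head.

**Training.** Adam (β = 0.9/0.999) at learning rate 1e−4 (3e−3 in the
desk-scale configuration, where the model is tiny and data scarce),
batch size 32, weighted cross-entropy with inverse-frequency class
weights w_c = N/(K·n_c) normalized by the batch's weight sum (so a
balanced batch reduces exactly to the unweighted loss). Under LOSO the
weights are computed once from the *cohort* counts and held constant
across folds (the canonical arithmetic — e.g. 88/(2·59) and 88/(2·29)
for a 59/29 split — uses cohort counts): re-deriving them inside each
fold makes the held-out subject's class the up-weighted training
minority in every fold, a systematic bias the null-cohort guard
exposes. Early stopping
halts after `patience` = 20 epochs (desk-scale: 8) without validation
improvement and restores the best-validation weights; max 200 epochs
(desk-scale: 25). All randomness (initialization, shuffling, dropout)
derives from seeded NumPy generators, so training is bit-reproducible.

Two ablation variants keep depth and parameters comparable:
`conv_bn` replaces the residual blocks with conv–batch-norm–ReLU stacks
(restoring the train/inference batch-statistic mismatch the
normalizer-free design avoids — in training mode its outputs depend on
the batch composition, which a test demonstrates), and `nfnet_no_attn`
drops the attention module.

**Attention allocation.** For interpretability at the group level, an
epoch's attention distribution is attributed to a set of target fused
rows (e.g. the delta rows 4–7) in proportion to those rows' share of
the total |r| mass at each time step; the score is the
attention-weighted mean attribution in [0, 1], averaged over a
subject's epochs. Frames with zero total mass contribute 0.

## Evaluation protocol (`pipeline`)

**LOSO.** One fold per subject; the held-out subject's epochs are never
seen by any fitted component. Within each fold the remaining subjects
are split 8:2 into training and validation *by subject*, stratified by
class (classes reduced to a single subject fall back to training with a
warning; whether the original protocol stratified is unstated — we
stratify). Microstate templates are clustered from the pooled GFP-peak
maps of the training subjects only (not the validation subjects — the
strictest reading of fold-internal extraction), and all subjects in the
fold are backfit against those fold templates. An audit log records the
template/train/validation subject sets per fold, and the test suite
asserts the test subject never appears there. Whether templates should
be per-subject-then-aggregated or pooled is not fixed by the protocol;
pooling across training subjects is used.

**Majority voting and vote calibration.** A subject's label is the
modal epoch vote; ties break to the higher mean predicted probability,
and a residual exact tie goes to the disease-positive class (stage 1:
dementia, stage 2: FTD) — favouring screening sensitivity; with an even
epoch count ties are possible and some rule is required. Epoch votes
are by default thresholded at the midpoint between the two classes'
median *validation* scores rather than at a fixed 0.5
(`calibrate_votes`). Rationale: any classifier trained on a LOSO fold
carries a small constant output bias tied to the fold's class
composition; because every epoch of a subject shifts together, majority
voting amplifies even a ±0.03 constant into deterministic subject-level
decisions. On uninformative (null) data this produces systematically
above- or below-chance LOSO accuracy depending on the weighting scheme;
the validation-derived threshold tracks the fold constant and cancels
it, while on separable data it sits centrally between the score
clusters. It uses only validation epochs — never the test subject.
Setting `calibrate_votes=False` restores plain argmax voting.

**Cascade.** Stage 1 screens dementia vs HC; subjects screened positive
receive the stage-2 AD/FTD call. Stage-2 metrics are computed LOSO on
the true patients; screening false positives are routed through a
fallback stage-2 model trained on all patients (no leakage — an HC
subject never contributes to stage-2 training). The composed 3-class
balanced accuracy is the mean of the three class recalls of the
composed confusion.

**Metrics and statistics.** Balanced accuracy is the arithmetic mean of
per-class recalls. AUC uses the rank statistic with midranks for ties;
the Youden threshold maximizes sensitivity + specificity − 1 over
pooled LOSO out-of-fold scores post hoc (reported, never fed back into
training), ties resolved toward higher sensitivity. McNemar's exact
test: p = min(1, 2·P(X ≤ min(b, c))), X ~ Binomial(b+c, ½). The
Friedman statistic uses within-block midranks without the
tie-correction denominator (slightly conservative; a warning flags
ties). Benjamini–Hochberg step-up adjustment covers all pairwise band
comparisons jointly. Mann–Whitney U is exact for ≤ 8 observations per
group without ties, otherwise normal-approximated with tie correction
(threshold configurable).

## Synthetic cohorts (`synthetic`)

The generator produces 19-channel recordings as

    x(t) = Σ_bands a_b(t)·sin(2π f_b t + φ_b) · m_{L(t)} + ξ(t)

with L(t) a piecewise-constant latent state over the four dipolar
prototypes (segment durations uniform on 60–120 ms, transitions uniform
over the other three states), f_b each band's geometric-mean frequency,
a_b(t) a slowly amplitude-modulated baseline, and ξ spatially white
Gaussian noise. Baseline amplitudes emulate awake eyes-closed rest:
alpha-dominant (1.0) with weak slow activity (delta 0.10, theta 0.25,
beta 0.20, gamma 0.08) at noise SD 0.40 — deliberately weak baseline
delta, because spatial correlation is amplitude-invariant: pathological
bursts are visible to the soft sequences only where the baseline
topography in that band is noise-dominated.

Class effects (defaults in parentheses; all are free parameters of the
cohort spec, not claims about effect sizes in patients):

* **HC** — none.
* **AD** — alpha carrier multiplied by the attenuation factor (0.25),
  diffuse theta elevation (×1.8), and Poisson-scheduled broadband delta
  bursts (10/min, 0.2–0.4 s, Hann-windowed, gain 4) riding whatever
  template is active.
* **FTD** — mild generalized slowing (alpha ×0.55; alpha is relatively
  preserved compared to AD but reduced against HC, which is what makes
  a unified "dementia" screening class learnable), plus delta bursts
  locked to Class-C periods: Poisson windows of 0.5–1 s during which
  the latent state is held at C and a frontally weighted Class-C
  topography (frontal gain 3) carries the delta burst — the "frontal
  shift". The ground-truth sequence reflects the forced C periods.

Per-subject seeds derive deterministically from the cohort seed and
subject index (`numpy` SeedSequence spawning), so cohorts regenerate
bit-identically. Cohorts export as EDF (a minimal 16-bit writer with
1-second records; per-channel full-scale physical ranges; reads back
through standard EEG toolchains) plus JSON sidecars carrying the
run-length-encoded state sequence.

**What the generator does not emulate:** volume conduction and head
geometry, artifacts (EMG, blinks, electrode drift), non-stationary
background spectra, inter-subject montage variability, and realistic
effect-size distributions. Passing the synthetic end-to-end benchmark
therefore demonstrates that the pipeline is leakage-free, that its
stages learn the signatures they were designed around, and that the
machinery is numerically sound — it does not predict clinical
performance on patient EEG.

## Problem sizes and reproducibility

The end-to-end benchmark uses a 12-subject cohort (4 per class), 35 s
per subject (5 epochs each), the reduced model width, and ≤ 25 training
epochs per fold; the null (leakage-guard) cohort uses 10 subjects with
every class effect switched off and ≤ 10 epochs per fold. These sizes
were chosen so the whole suite runs on a single CPU in minutes while
leaving the architecture (kernel sizes, strides, heads, 2560-sample
epochs, 320 tokens) untouched. On the null cohort, subject-level
accuracy is expected inside the 95% binomial band around chance — a
systematic excess would indicate hidden leakage.

## Known limitations

* The exact block count/widths of the original architecture are not
  public; widths here are configurable defaults.
* No microstate segmentation smoothing (temporal regularization) and no
  polarity-sensitive variants.
* The EDF writer requires integer sampling rates and whole-second
  recordings (trailing samples are truncated with a warning).
* Attention is taken post-softmax and averaged over heads and queries;
  other roll-ups (per-head, pre-softmax) are not exposed.
* Signed (polarity-sensitive) soft sequences are available but untested
  against any downstream claim.
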