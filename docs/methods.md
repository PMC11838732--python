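# Methods

`mriclip` implements a hierarchical vision-language model for multi-sequence
3D MRI studies, together with the phantom-study generator that makes every
stage testable end to end on one CPU. This note records the model, the
generator's assumptions, the numerical choices, and what the desk-scale
results do and do not demonstrate.

## Model

**Volume tokenization.** Each 3D sequence is tiled into fixed-shape patches
(zero-padded at boundaries; desk preset 8×8×4, full-scale preset 32×32×4).
Patches whose fraction of above-background voxels does not exceed a
threshold are discarded ("background" = intensity below 5% of the volume
maximum; default threshold 0.05 — the filtering rule needs a concrete
background definition and this is ours). Remaining patches are compressed by
a VQ-VAE: a strided 3D convolutional encoder (kernel = stride, i.e.
non-overlapping, two blocks) maps the patch to a latent grid (desk 4×4×2,
full scale 8×8×2) with 2 channels per position; each position's channel
vector is snapped to the nearest codebook entry in L2 (ties to the lowest
index) with a straight-through gradient. Training minimizes L1
reconstruction plus the standard codebook and commitment terms (commitment
weight 0.25). A random axis-order permutation, drawn uniformly from the six
orders and applied per batch, encourages orientation invariance. At the
full-scale configuration the compression ratio is 16 (4096 voxels → 256
latent scalars). Quantization operates per latent position on the 2-channel
vectors, not on the flattened 256-vector: a codebook of 8192 entries over
2-dimensional vectors is the only reading under which both printed numbers
are consistent.

**Hierarchical encoder.** A sequence transformer encodes one sequence from
its tokens; a study transformer aggregates sequence representations. Each
token feature is the flattened quantized latent concatenated with a
30-dimensional sinusoidal positional feature of its 3D grid coordinate
(10 dims per axis, 5 sin/cos pairs, geometric frequency schedule over a base
of 100) and a 3-dimensional plane one-hot. The sequence-level input is
[learned registers | encoded sequence name | token features]; the sequence
representation is a linear projection of the concatenated final-layer
register outputs, and one parameter set serves all sequences. The
study-level input is [registers | encoded study name | projected sequence
representations]; the study representation concatenates the study register
outputs. Positional information enters only through explicit features, so
both levels are order-invariant (verified by test). At full scale the
sequence ViT is 15 layers × 16 heads × 64 dims (width 1024, 20 registers,
1024-d output) and the study ViT 4 layers × 8 heads × 64 dims; its internal
width of 512 conflicts with 1024-wide register outputs, so we project
1024→512 on input and 512→1024 per register on output, preserving both
printed facts (10 × 1024 = 10240-d study vector). Transformer style:
pre-norm, MLP ratio 4, GELU, registers initialized N(0, 0.02²). Variable
token counts are padded and masked; padded positions are never attended.

**Text encoders.** Reports are encoded by a small decoder-only
autoregressive word-level transformer pretrained with next-word prediction
on the synthetic report corpus; a report's embedding is the final-position
hidden state after the end token (last-token readout matches the
autoregressive pretraining). Sequence and study names are case-folded and
encoded character-wise by 3-layer transformers with mean pooling; unknown
characters map to a reserved symbol. The sequence-name encoder can be
pretrained contrastively against mean-pooled visual token embeddings. The
study-name encoder shares the architecture but is not pretrained (we follow
the prose description over a pseudocode comment that calls it an LSTM). All
text encoders remain trainable during contrastive training.

**Objective.** For a batch of k study-report pairs, logits are cosine
similarities scaled by exp(τ) (τ learnable, init 0.07); the loss is
cross-entropy toward the diagonal computed in both directions and summed.
The patient-discrimination term projects sequence representations through a
2-layer MLP, forms cosine logits divided by a learnable temperature τp
(init 0.1), sets self-logits to −10, softmaxes rows, and charges each row
−log(probability mass on its own study) weighted by 1/(study size); this
follows the executable convention, with a `strict_equation` flag for the
alternative that includes the self-pair in both numerator and denominator
and averages with a leading 1/k. The combined loss is clip + λ·patdis with
λ = 0.03. Augmentations (finding-order shuffling, per-token dropping,
"unk" name replacement, full-sequence dropping, ±50% filter-threshold
jitter; probabilities 0.5/0.1/0.1/0.1) are applied independently per pair;
at least one sequence and one token always survive and labels never change.
Abnormal studies are upsampled 4× in the epoch stream (normals keep census
multiplicity). Optimization is decoupled-weight-decay Adam with cosine decay
(floored at 15% of base), gradient clipping at 1.0, and a separate, larger
learning rate for the two scalar temperatures: the logit scale exp(τ) must
travel from 1.07 to order 10, and with a shared learning rate that journey
dominates the training budget at desk scale.

**Transfer heads.** Heads train on frozen study embeddings: 3-layer MLPs
for multi-label diagnosis and referral (positive-weighted binary
cross-entropy, weight = negatives/positives per label), 3-class acuity
(categorical cross-entropy), and age (L2; the scalar output is rescaled to
the train split's mean/SD so regression starts at the mean). Hidden width
is max(32, out_dim, d/4) — unstated upstream, ours. The best-validation
checkpoint is kept (earliest on ties). The probe protocol is stratified
5-fold CV with a 2-layer single-logit head; checkpoint selection uses an
internal split of the training fold so the held-out fold is only ever
scored (selecting on the evaluation fold inflates null AUROC by ~0.1 at
desk sizes).

**Explanations.** LIME perturbs one sequence by token removal: the first
mask is all-ones, the rest i.i.d. Bernoulli(0.5) with empty masks
resampled; the model's target-label logit per masked input is fitted by
weighted least squares with kernel exp(−(1−s)²/σ²), s = cosine between mask
and the all-ones mask, σ = 0.25 (a standard locality kernel for binary
masks; plain WLS with an optional ridge flag). Removal is implemented by
exclusion from the transformer input, which the attention mask makes
exactly equivalent to physical removal. Ranking ties break toward the
lexicographically lowest grid coordinate.

**Metrics.** Top-k retrieval uses stable sorting (ties to the lowest
index); grouped retrieval averages top-1 over random disjoint groups,
dropping the remainder. Multi-label AUROC is midrank-based; one-class
labels are reported as NaN and excluded from the mean with a warning. NPR
is the mean positive rate among a query's k = 20 nearest reference
neighbors divided by the reference base rate; neighbors are cosine
(matching the contrastive space), and a query's self is excluded when the
query set is the reference set. Priority scores are the softmax-expected
acuity class index rescaled to [0, 1]; correlation is Pearson by default
(Spearman behind a flag) with a Fisher-z 95% CI.

**Fairness.** TPR disparity is subgroup TPR minus population TPR. The
bootstrap test draws 200 patients with replacement from the subgroup and
200 diagnosis-matched patients from the population (matched to the group
draw's label frequency — the matching algorithm is ours), 20 iterations,
then a one-sided Mann-Whitney U with null "subgroup TPR is not less than
the population's". **Calibration regime:** this procedure is calibrated
only when subgroups are much larger than the 200-patient draws, as in a
~30k prospective cohort, where we measure a 5% type-I rate; in cohorts of
a few hundred the subgroup's own sampling error shifts the entire bootstrap
distribution and false-positive rates reach ~50%. The calibration tests
therefore use prospective-scale synthetic tables. Turnaround-time audits
use Fisher's exact test per attribute level against the modal level with
Haldane-Anscombe-corrected odds ratios, Woolf 95% CIs, and Holm family-wise
correction (Bonferroni optional). The superiority sample-size formula is
the two-group normal approximation with one-sided α; p = 0.78 both arms,
margin 0.02, α = 0.01, power 0.90 reproduces 22,338.

## The phantom generator

The generator is the study's data source, so its defaults define the test
conditions. Each study has 2–4 sequences with heterogeneous shapes
(32×32×16, 32×32×12, 24×24×16 at desk scale), random planes and
orientation codes, per-type contrast factors, and Rician-style magnitude
noise (|signal + complex Gaussian|, SNR 20). The head is an ellipsoid with
smooth texture whose scale shrinks linearly with age (0.4% per year from
age 20, noise equivalent to 5 years — matching the scale of reported
brain-age errors), making age recoverable from imaging alone. Four diagnosis
classes plant geometric lesions at recorded voxel locations: a homogeneous
bright sphere ("tumor"), a very bright rim around a dark core ("abscess",
additionally boosted on diffusion-type sequences), the brightest striped
paired ellipsoids ("ventriculomegaly"), and a moderate wedge sector
("infarct", diffusion-boosted). Each class is visible only in a
class-specific set of sequence types, and the sequence-type draw guarantees
at least one sequence that can show each planted class.

The distinct amplitude signatures are a deliberate design decision: lesions
are larger than one patch, so after 4× latent compression the interiors of
purely *geometric* classes (sphere vs ring vs wedge) are mutually
indistinguishable at the token level — we verified this directly with
token-level probes — and no desk-scale training budget can recover what the
representation does not contain. Amplitude-plus-shape signatures keep the
per-token class information while preserving the geometric ground truth
needed for localization scoring.

Reports use the fixed grammar "<class> in <left/right>
<frontal/occipital> <superior/inferior> region", rendered as a numbered
list ("1. no acute intracranial abnormality" for normals), which keeps the
text-encoder vocabulary small and ties report content to image content
(class identity and lesion octant). Acuity derives from a configurable
label→{normal, medium, high} table (tumor/infarct high, abscess/
ventriculomegaly medium; the upstream mapping table is not public);
referrals from a label→referral table over three services. Subgroup
attributes (region, schedule, sex, insurer, scanner, age band) are drawn
from fixed categorical distributions; turnaround times are short
(uniform < 7 d) or long (7 d + exponential) with the long-side odds
optionally multiplied per attribute value, so a planted odds ratio is
recoverable by the audit.

**What the phantoms do not emulate:** anatomy, contrast physics, scanner
artifacts, report language variability, correlated comorbidities, and
realistic class imbalance. Passing desk-scale tests demonstrates that the
pipeline's machinery — tokenization, alignment, transfer, attribution,
auditing — is implemented correctly and can recover planted structure; it
says nothing about performance on clinical MRI.

## Problem sizes and numerical choices

The shared desk run uses 200 studies (independent per-class prevalence
0.3, so ~24% normals), an 800-patch VQ training set (10 epochs), 8 report-
LM epochs, and 40 epochs of contrastive training at batch 24 with the diagnosis,
referral, acuity and age heads trained on the frozen embeddings of the
160/40 train/validation split. These sizes were chosen so a full run with
tests completes comfortably on a single CPU while leaving the learning
problem non-trivial (held-out retrieval starts at 2.5% chance). Further
choices: float32 throughout the network stack; probability clamping at
1e-7 in the BCE metric; quantization distances computed in float64;
attention masking via −1e9 additive bias; LIME fits use 500 masks at desk
scale (3000 at full scale) — coefficients of affine models are already
exact to 1e-6 at 500.

## Known limitations

- The network stack is a minimal numpy autodiff engine built for this
  package: single-threaded, no GPU, no kernel fusion. Full-scale presets
  are exercised for shape contracts and forward passes, not trained.
- The VQ codec's convolutions are non-overlapping (kernel = stride); this
  realizes the stated downsampling exactly but has no cross-patch-cell
  receptive-field overlap.
- The bootstrap fairness test should not be trusted in small cohorts (see
  calibration regime above).
- Desk-scale contrastive training is variance-prone: retrieval metrics on
  a 40-study validation set move in steps of 2.5%.
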