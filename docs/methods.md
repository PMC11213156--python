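# Methods

## The model

`neurofuse` implements a generative multimodal classification framework
for the Alzheimer's disease continuum with three stages.

**Feature reduction.** Each input channel has its own CNN encoder mapping
it to a latent vector of shared width *d* (default 100):

* sMRI — gray-matter probability volumes (reference size 121×145×121)
  through a 3D CNN: six convolutional layers (3×3×3 kernels for the first
  four, 2×2×2 for the last two; 64, 64, 64, 128, 128, 128 filters), three
  max-pooling stages, four fully-connected layers (1536, 768, 384, 192)
  and a final linear projection to *d*;
* rs-fMRI — the static functional network connectivity (sFNC) vector:
  Pearson correlations between 53 IC time courses, strict upper triangle,
  row-major, length 1378; through a 1D CNN (four conv layers, kernel 5;
  64, 128, 128, 128 filters; two poolings; FC 384 → *d*);
* SNPs — minor-allele dosages in {0, 1, 2} (reference: 565 SNPs) through
  three conv–batchnorm–maxpool blocks (kernel 3; 64, 64, 128 filters),
  FC 1024, 512, 128 and a projection to *d*.

ReLU activates all encoder layers. Convolutions use stride 1 with "same"
zero-padding for odd kernels and no padding for even kernels; pooling is
window 2, stride 2. The printed FC widths end at 192/128 for the
sMRI/SNP stacks while the latent is 100-wide, so a closing linear
projection reconciles the two; the fMRI stack's last FC layer *is* the
latent. Pooling positions (after conv 2/4/6 for sMRI, 2/4 for fMRI, one
per SNP block) are this package's choice of evenly spaced downsampling
and are configurable through `EncoderSpec`.

**Generative module.** Two Cycle-GANs bridge the latent spaces
sMRI↔fMRI and sMRI↔SNP. Generators are MLPs (256, 512, 512, 1024, 512
hidden units, ReLU, linear output at width *d*); discriminators are MLPs
(256, 128, 64, 1) with LeakyReLU and dropout 0.3. The objective combines
an adversarial term — least-squares by default, binary cross-entropy by
config — with L1 cycle consistency in both directions, weight
`cycle_loss_weight` (default 10). One discriminator step then one
generator step per mini-batch; Adam, learning rate 1e-4. There is no
fMRI↔SNP pair; a subject missing sMRI cannot be routed by default, and
`allow_chained_bridges` enables two-hop imputation (e.g. fMRI → sMRI →
SNP) for that case.

Because neither the adversarial nor the cycle term ever sees the
subject pairing, cross-domain maps are identifiable only through
distributional structure (in practice: the strong class clustering of
encoder latents). The imputation tests construct their latents
accordingly.

**Fusion and classification.** The three latents are concatenated (3·*d*
= 300 features) and classified by an MLP (150, 75, 2; ReLU; softmax).
When a modality is missing its latent is produced by the corresponding
frozen generator, and the provenance (encoded vs generated, with source)
is recorded per channel.

## Training scheme

Training is two-step, never end-to-end across the generative module:

1a. Bi-modal models (sMRI+fMRI; sMRI+SNP) are trained for CN-vs-AD on
    the subjects sharing both channels: stratified 10-fold CV, 40 epochs,
    Adam lr 1e-4, batch sizes 14 and 9, weighted cross-entropy with
    class weights N/(K·n_c). The best fold by validation accuracy (ties:
    lower validation loss, then lower fold index) supplies the encoders.

1b. Latents extracted by those encoders train the two Cycle-GANs for 600
    epochs, reusing the bi-modal mini-batch composition (same subjects
    per batch); the best fold's held-out subjects provide per-epoch
    imputation MAE, reported per direction.

2.  The full three-channel framework trains on the complete CN/AD cohort
    (80/20 stratified train/test split; stratified 10-fold CV on the
    training portion; batch 12; 70 epochs) with the four generator
    weight sets frozen — only encoders and the fusion head receive
    updates, audited by weight checksums before and after. Mini-batches
    are grouped by availability mask and routed per group; gradients flow
    *through* frozen generators into the source encoder.

Evaluation reports accuracy, precision and recall from stored confusion
counts, with the patient class (AD, or MCIc for Task 2) positive — a
convention this package fixes, since either choice is defensible. Task 2
(MCIc vs MCInc) evaluates the Task-1-trained model on the full MCI
cohort, which never appears in any training fold. Generalization is
probed by independent runs reshuffling the split (default 5), reported
as mean ± sd. Baselines are an ensemble SVM (bagging of 10 RBF SVCs) and
a random forest, over flattened concatenated features with mean or zero
imputation fitted on training rows only.

## Interpretability

Integrated Gradients attributes the prediction of each test subject
jointly over the three channels along one straight path from a baseline
triplet — zero volume, zero connectivity vector, and a Gaussian-noise
dosage vector drawn once per run from a dedicated seed. The path
integral uses a right-Riemann sum with `ig_steps` points (default 64);
the completeness residual Σᵢ IGᵢ − (F(x)−F(x′)) is recorded per subject
and shrinks like 1/m. The attribution target F is the logit of the
predicted class (probability optionally, by config); logits avoid
softmax saturation. Attribution requires all three channels present.

Selection rules follow the channel sizes: voxels above the 99.5th
percentile of the per-map |IG| distribution; connections above the 98th;
SNPs above the 65th *and* positive. Percentiles are linear-interpolated
order statistics and "exceeding" is strict; the scope is per subject per
map by default with a pooled-over-subjects option, since either reading
of "the respective IG values distribution" is defensible. Thresholded
sMRI maps are averaged within atlas regions; a region is retained when
at least 99% of subjects have a surviving average in it. Surviving
connections map back to component pairs (inverting the row-major
vectorization) and to the seven resting-state networks, flagged
intra/inter.

Group validation compares per-feature attribution values across CN, AD,
MCInc and MCIc: Shapiro–Wilk normality p-values are reported as a
diagnostic (the pipeline is nonparametric regardless); Kruskal–Wallis at
α = 0.05 gates six pairwise two-sided Wilcoxon rank-sum contrasts
(AD-CN, AD-MCIc, AD-MCInc, CN-MCIc, CN-MCInc, MCIc-MCInc), Bonferroni-
adjusted with family size 6 (optionally contrasts × features). Exact
rank-sum p-values are used for small tie-free samples. Groups with fewer
than three observations skip the feature with a logged warning.

## Synthetic cohorts

The simulator generates the statistical structure the framework assumes,
not realistic physics. Per subject, shared latent factors z (default 5)
drive all channels:

* GM volume = smooth baseline field + Σ z·(smooth loading maps) − class
  effect + N(0, σ²) noise, where the class effect reduces mean intensity
  by `delta_gm` inside designated atlas regions, scaled by a severity
  multiplier per class (CN 0, MCInc 0.25, MCIc 0.6, AD 1);
* IC time courses ~ MVN with a correlation matrix carrying severity- and
  factor-scaled shifts `delta_fnc` on designated component pairs,
  projected to the nearest correlation matrix (eigenvalue clipping +
  diagonal rescaling) before Cholesky sampling;
* SNP dosages ~ Binomial(2, p) with allele frequencies of designated
  SNPs shifted by a severity-scaled `delta_af` (error if outside (0,1)).

Effects are additive on generating parameters, so closed-form expected
values exist for testing. Atlases are Voronoi parcellations inside an
ellipsoidal mask (labels 1..n, background 0, every parcel non-empty).
Missingness is sampled independently per subject within class (MCAR);
the default per-class rates follow the study cohort for the MCI groups
(MCInc: 59.6% missing SNPs, 60.1% missing fMRI; MCIc: 30.8% and 92%) and
use 50%/35% (fMRI/SNP) for CN and AD, whose per-class rates are not
published. `imaging_effect_prob < 1` makes patients express each imaging
effect independently with that probability while the genetic effect is
constitutive — a simple model of heterogeneous presentations that
forces a classifier to consult all channels.

What the simulator does *not* emulate: spatial covariance of real
atrophy, hemodynamics, linkage disequilibrium, population structure,
site effects. Passing recovery tests therefore demonstrates that the
pipeline's machinery is sound — signals planted under the model's own
assumptions are found — not that comparable performance holds on
clinical data.

## Problem sizes and numerical choices

Reference dimensions and training constants default to the study values
(121×145×121 volumes, 53 ICs, 565 SNPs, latent 100, epochs 40/600/70,
batches 14/9/12, 10 folds, 5 runs). The desk-scale presets used by the
test suite and the acceptance script shrink the cohort to 12×12×12
volumes over 30 atlas regions, 10 ICs (45 connections), 50 SNPs, latent
width 16, narrower generators (64, 128, 128, 256, 128), 3 folds and
30/150/70 epochs; the recovery cohort plants effects in 2 regions,
3 connections and 2 SNPs (severity-scaled δ_gm 0.3, δ_fnc 0.5, δ_af 0.7
from base allele frequency 0.15) with `imaging_effect_prob` 0.7 and
training-time missingness of 30% fMRI / 20% SNP in CN/AD, so the fusion
head learns to consume generator-imputed latents.

At desk scale the scaled sMRI and SNP encoders omit max-pooling: on
small grids the pooled maximum wanders between subjects, which blurs
gradient-based attribution without helping accuracy. The full-resolution
reference encoders are validated through symbolic shape inference
(`encoder_layout`); their first fully-connected layer holds on the order
of 10⁹ weights and is never materialized here.

Other numerical choices: He-initialized weights from a per-build seeded
generator; Adam (β₁ 0.9, β₂ 0.999, ε 1e-8); batch-norm momentum 0.9 with
running statistics at evaluation; constant IC time courses are errors
rather than NaN sources; correlation matrices are clipped to [−1, 1]
after `corrcoef`; dosage tables validate every entry in {0, 1, 2} and
name the offending row/column.

## Known limitations

* Attribution recovery concentrates on channels the trained classifier
  relies on. When cross-channel signal is redundant the optimizer may
  ignore a channel entirely, and its attributions are then noise — a
  property of gradient-based attribution, not a defect of the
  implementation. The SNP channel is the most affected at desk scale:
  its designated SNPs rank in the top quartile of group-mean |IG| but
  not reliably in the top decile, because the fixed Gaussian-noise
  baseline contributes a model-systematic |x−x′| noise floor that
  subject averaging cannot remove.
* Cycle-GAN imputation learns distribution-to-distribution maps; per-
  subject fidelity depends on how strongly the latent distributions pin
  the correspondence. Heterogeneous cohorts (imaging-silent patients)
  raise the irreducible imputation error.
* The per-fold behaviour of "best model by validation accuracy" with
  from-scratch re-initialization means fold models are not comparable
  checkpoints of one trajectory; warm starting from Step 1a is available
  by config but is not the default.
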