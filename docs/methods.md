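# Methods

## The classifier

The package implements a two-channel multimodal classifier for binary
Alzheimer's-disease diagnosis (control vs. AD) from paired structural brain
MRI and SNP genotype data.

**Imaging channel.** A five-stage 3D CNN over a normalized T1 volume whose
side lengths are divisible by 2^5 (the published operating point is
128x128x128; synthetic work here uses 32x32x32). Each stage is a 3x3x3
convolution with stride 1 and symmetric zero padding 1 (so convolution
preserves spatial extent), ReLU, and non-overlapping 2x2x2 max pooling with
stride 2. Filter counts are [4, 8, 16, 32, 32]. The final feature map is
flattened — width (side/32)^3 x 32 — and passed through three dense layers
of widths [128, 32, 16], giving a 16-dimensional imaging embedding. Dropout
(rate 0.2) is applied after each hidden dense layer. We deliberately do
*not* drop voxels of conv feature maps: when the class signal is spatially
localized, deep feature maps carry it in a handful of positions and spatial
dropout deletes it often enough that optimization never leaves the
chance-level plateau (we observed exactly this failure mode); dense-head
dropout is also the convention of the 3D-CNN literature this architecture
follows.

**Genetic channel.** The input sequence is the dosage codes {0,1,2} of the
SNP panel selected by Fisher screening, with the APOE e4 allele count
appended as the final token. Token embeddings are 16-dimensional; the APOE
position indexes a separate 3-row embedding table (the APOE genotype comes
from a different assay and carries far larger effect, so it earns its own
vocabulary), and a learned positional table of length `seq_len` is added.
Two pre-norm Transformer encoder layers follow (4 heads over the
16-dimensional representation, position-wise feed-forward width 32, dropout
0.2 on the attention and feed-forward sub-layer outputs), then mean pooling
over positions and a linear map to the 16-dimensional genetic embedding.

**Fusion and head.** The two embeddings are combined coordinate-wise by
multiplication; an MLP with two 16-unit ReLU hidden layers and a softmax
over K = 2 produces class probabilities. Restricted variants bypass fusion
and feed a single channel's embedding to the same head. The loss consumes
the pre-softmax scores through a log-sum-exp formulation; the probability
contract (rows summing to 1) holds at the interface.

**Initialization.** Fan-in-scaled Gaussian weights (He scaling before ReLU,
1/fan-in otherwise), zero biases, 0.02-sd embeddings — with one deliberate
exception: the output biases of both channel embeddings start at 1, i.e. at
the multiplicative identity of the fusion. With zero-mean embeddings the
product fusion attenuates each channel's gradient by the other channel's
(initially near-zero) magnitude and joint training starts an order of
magnitude slower than single-channel training; starting at the identity
makes fusion locally additive and removes the attenuation.

All tensors are float32; gradients are hand-derived per layer and verified
against central finite differences in float64 (tests/test_nn_gradients.py).

## SNP pre-selection

Every SNP is tested against the diagnosis with the Freeman–Halton extension
of Fisher's exact test on the 2x3 diagnosis-by-dosage table: the two-sided
p-value is the sum of multivariate-hypergeometric probabilities (all
margins fixed) of every table whose probability does not exceed the
observed table's, with a 1e-12 relative tolerance applied toward inclusion.
Monomorphic tables return p = 1. Tables are enumerated over the two free
cells and evaluated in log-gamma space; enumeration refuses totals above
10,000 by default. SNPs with p < alpha (default 0.01, strict, no
multiple-testing correction) are retained in genomic order, and APOE e4 is
appended exempt from the threshold. A 2x2 allelic mode (alternate vs.
reference allele counts, scipy's exact test) is available behind a flag.
Selection defaults to training-partition subjects to keep validation and
test data out of every fitted quantity; a whole-cohort mode exists for
compatibility with protocols that screen before splitting.

## Training protocol

Categorical cross-entropy; AdamW with beta1 0.9, beta2 0.999, eps 1e-8,
constant learning rate 1e-3, decoupled weight decay 0.01 applied to
matrices only; batch size 16 with the final partial batch kept; shuffling,
dropout and initialization draw from independent seeded streams, so a run
is bit-reproducible on one platform. After each epoch the monitored
quantity (validation loss by default; negated validation AUC-ROC as a
config option, appropriate when the reported endpoint is a ranking metric)
is compared against the best so far with absolute tolerance 1e-6; early
stopping fires after `patience` (default 3) epochs without strict
improvement, capped at `max_epochs` (default 100), and the best snapshot —
not the last — is returned.

## Evaluation

Threshold metrics (accuracy, precision, recall, F1) use p(AD) >= 0.5, the
argmax rule of a two-class softmax; precision and F1 report 0 with a
warning when their denominators vanish. AUC-ROC is the rank formulation
with ties counted one half; AUC-PRC is average precision, the exact area of
the step-shaped precision-recall curve in decreasing-score order — step
interpolation is deliberate, as trapezoidal PRC interpolation is
optimistically biased, and the convention is recorded in the metrics
output. Both curves are emitted as point lists. Two ensembles combine the
single-channel variants: probability averaging, and a conjunctive vote that
labels AD only when both channels do (for which ranking areas are not
meaningful).

## Synthetic cohort generator

The generator emulates the shape of the motivating case-control study — 379
subjects, 174 AD vs. 205 controls, dosage-coded SNPs with one strong
APOE-like locus among many nulls — so the whole pipeline is exercisable
without restricted data.

*Genotypes.* Per SNP j, an allele frequency p_j ~ Uniform(maf_range)
(default 0.05–0.5) and independent dosages Binomial(2, p_j) per subject
(Hardy–Weinberg equilibrium; no linkage disequilibrium — SNPs are
independent). The APOE-like locus is generated the same way at frequency
0.2.

*Labels.* A logistic liability: l_i = b0 + sum_j beta_j d_ij +
beta_APOE e4_i + Logistic(0,1) noise, with the intercept b0 solved by
bisection so the expected AD count equals the target (174/379 by default);
label = 1 iff l_i > 0. Defaults: five causal SNPs at log-odds 0.5 each and
APOE log-odds 1.2.

*Volumes.* A smooth ellipsoidal "brain" phantom (background 0.05, tissue
0.75 with a sigmoidal rim) plus a spatially correlated noise field — white
Gaussian noise smoothed with a sigma-1.5-voxel kernel and rescaled to
`noise_sd` (default 0.1). Spatial correlation matters: with white voxel
noise every subject carries a high-frequency fingerprint that a CNN
memorizes in preference to the class signal, which preprocessed,
down-sampled MRI does not exhibit. A fixed, slightly off-center cubic ROI
(side `roi_fraction` x volume side, default 0.1) stands in for a
hippocampus-like atrophy target: its intensity is multiplied by
(1 − atrophy_effect · m_i)(1 + b_i), where m_i = coupling · sigma(b0+eta_i)
+ (1−coupling) · label_i mixes liability-driven and label-driven signal
(default coupling 0.5), and b_i ~ N(0, roi_between_sd) (default 0.15) is
subject-level anatomical variability of ROI brightness, independent of
disease. Without b_i the planted effect is essentially noiseless (the ROI
mean discriminates labels with AUC ≈ 1 even at small atrophy_effect) and a
trained imaging channel is either at chance or at ceiling; the
between-subject term gives the modality a finite, controllable effect size
d ≈ atrophy_effect · Δm / roi_between_sd. Voxels are clipped to [0,1] and
stored as 0–255 integers, the format the readers expect.

What the generator does *not* model: real neuroanatomy, deformation-based
atrophy (intensity reduction is the stand-in), scanner artifacts, linkage
disequilibrium, population structure, relatedness. Passing tests therefore
demonstrate that the pipeline recovers planted signal of the stated form at
desk scale, not clinical performance.

## Study-scale choices in the test suite

CPU-scale substitutes for the published operating point, chosen once:

- Volumes are 32^3 (the architecture's minimum) throughout the suite; 128^3
  is exercised only through the parameter-count closed form, which the
  acceptance script cross-checks against an instantiated model.
- The multimodal-advantage experiment uses n = 400 subjects, five seeds,
  and a fixed 24-epoch budget per variant with best-validation-loss
  snapshot selection. Its generator settings (genetics at the defaults;
  roi_fraction 0.2, atrophy_effect 0.8, roi_between_sd 0.65, coupling 0.5)
  make each channel informative but imperfect and partly complementary —
  the regime the two-channel design is built for. The imaging settings
  separate two concerns deliberately: the raw ROI contrast (atrophy_effect,
  kept high so the CNN engages within the epoch budget even inside the
  jointly trained model, whose channels engage sequentially) and the
  discriminability ceiling (contrast over roi_between_sd, kept moderate so
  a single channel cannot saturate and fusion has headroom). At 32^3 with
  the default 3-voxel ROI and default effect sizes the imaging channel does
  not leave its chance-level plateau within any desk-scale budget, so a
  comparison there would measure optimization failure rather than fusion.
- Null-calibration and null-training checks run at n = 160–200 with the
  cheap genetic-only or reduced configurations.

## Numerical notes and limitations

- The exact-test tolerance (1e-12, toward inclusion) makes tied table
  probabilities count into the p-value, the conservative direction.
- Max-pool gradients route to the argmax winner; ties (measure-zero for
  continuous inputs) go to the first index.
- Early-stopping improvement uses absolute tolerance 1e-6.
- The pooling stride of the published architecture is read as 2 (standard
  non-overlapping pooling); a literal stride-1 pooling cannot reduce a
  128^3 volume to a 16-dimensional embedding within the stated parameter
  budget. The three imaging dense widths and the encoder feed-forward width
  are not published; [128, 32, 16] and 32 keep the total budget at 0.32M
  parameters, under the published 0.58M.
- Training at 1e-3 with this architecture shows a characteristic plateau at
  ln 2 before the imaging channel engages; with small cohorts and short
  patience the stopper can fire inside the plateau. This mirrors the
  general brittleness of training small CNNs from scratch and is why the
  fixed-budget protocol exists for the fusion experiment.
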