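# Methods

## Problem and labeling model

Orthodontic skeletal classification assigns a lateral cephalogram to sagittal
Class I, II or III from the ANB angle: the angle at nasion (N) between the
rays to A-point (maxilla) and B-point (mandible). `fedceph` computes the
*signed* angle — from the ray N→B to the ray N→A, counter-clockwise positive
in an x-right/y-up frame — because Class III is defined by ANB values *below*
the lower threshold, including negative angles, which an unsigned angle can
never produce. Image pixel coordinates (y growing downward) are the default;
the y components are negated before the computation (`y_axis="down"`).
Consequence: a correct sign requires a facing-right lateral orientation;
a mirrored radiograph negates the angle.

Two threshold standards are built in and are attached per client, since
different clinics label under different conventions:

| standard | Class I band | Class II | Class III |
|---|---|---|---|
| `steiner` | [3.2°, 5.7°] | > 5.7° | < 3.2° |
| `kim` | [0°, 4°] | > 4° | < 0° |

Both band endpoints are included in Class I: the conventions state Class II
strictly "exceeding" the upper threshold and Class III strictly "falling
below" the lower one, leaving the closed band to Class I. In the 19-landmark
annotation layout A, N and B are the 5th, 2nd and 6th points (1-based); a
3-line file is read in A, N, B order. Classes carry stable integer codes
1/2/3 and model-target indices 0/1/2 (I→0, II→1, III→2 everywhere).

## Classifier architectures

The backbone is a densely connected CNN: 7×7/stride-2 stem convolution with
3×3/stride-2 max pooling, dense blocks whose layers concatenate
`growth_rate` new channels (bottleneck 1×1 at 4× growth) onto all previous
ones, and transition layers (1×1 convolution + 2×2 average pooling) between
blocks. The transition compression factor is 0.5 and the bottleneck width
4×growth — the canonical values for the 121-layer configuration, which with
block layout [6, 12, 24, 16] and growth 32 produce per-block channel counts
256/512/1024/1024 and a 1024-channel final feature map. A `tiny` preset
([2, 2] blocks, growth 8, 64×64 grayscale input, 32 final channels) supports
CPU-scale experiments; every head attaches to it unchanged.

Six heads consume the final (post batch-norm + ReLU) feature map `F`
(C×H×W):

- **plain** — global average pooling, FC to 3 logits.
- **channel attention (CA)** — gate `σ(MLP(avgpool(F)) + MLP(maxpool(F)))`
  where both pools collapse H×W per channel and the one-hidden-layer MLP
  (ReLU hidden, width C/r) is shared between the two descriptors.
- **spatial attention (SA)** — channel-wise mean and max maps stacked into a
  2×H×W descriptor, convolved with a single 7×7 kernel at stride 1 and
  zero-padding 3 (the only padding that preserves H×W), then sigmoid.
- **squeeze-and-excitation (SE)** — global-average squeeze to a length-C
  descriptor, excitation `σ(FC(ReLU(FC(z))))` at bottleneck width C/r.
- **SA_SE** — spatial attention first, then squeeze-excitation on the
  rescaled map (order configurable).
- **SPP** — spatial pyramid pooling at grid sizes [4, 8, 16] (adaptive
  average pooling, floor/ceil half-open bins), concatenated into a
  fixed-length vector of width C·Σs² feeding the FC directly.

Attention application is multiplicative: gates broadcast over the missing
axes and rescale `F` elementwise; CA/SA/SE/SA_SE then apply global average
pooling before the FC. The reduction ratio r defaults to 16 (the value of
the attention blocks' source designs), clamped so the hidden width is ≥ 1
(the tiny backbone uses an effective hidden width of 2). With gates
saturated at 1 every augmented variant reduces exactly to the plain head —
a tested invariant.

All of this runs on a compact reverse-mode autodiff engine over numpy
(`fedceph.nn`): float64 throughout, im2col convolutions, biased-variance
batch normalization with running statistics, and Adam with standard bias
correction. Every primitive's gradient is validated against central finite
differences in the test suite; the attention/SPP math is additionally pinned
to brute-force loop oracles at 1e-6 relative tolerance.

## Federated protocol

The FedAvg simulation runs clients sequentially in process. Per round the
server broadcasts the full parameter vector (weights *and* batch-norm
running statistics, so the aggregated model is self-contained); each client
trains `local_epochs` epochs on its own data (Adam, lr 0.001, cross-entropy,
batch 64 — all configurable) and returns its vector with its sample count;
the server takes the sample-count-weighted mean over clients that succeeded,
excluding failed clients and renormalizing the weights. Optimizer state is
client-local and reset each round — only parameters cross the wire. The
per-client batch-shuffling stream depends only on (client seed, round
index), which yields three exact identities kept under test: a single-client
federation is bit-identical to sequential training; identically configured
clients make the aggregate equal either update; zero learning rate freezes
the parameters for any number of rounds. Full-scale defaults are 50 rounds ×
5 local epochs; local/centralized training defaults to 100 epochs.

## Settings and evaluation

- **LL** trains one model per client on its local data; **CL** trains one
  model on the pooled data; **FL** runs the protocol above. All settings
  evaluate on the merged test pool (FL also logs per-client test
  breakdowns and a per-round accuracy series).
- Metrics: accuracy, support-weighted precision/recall/F1 (weighted recall
  equals accuracy by construction — tested), Cohen's kappa (the degenerate
  single-marginal case is defined as 1 for perfect agreement, else 0), the
  unweighted mean of one-vs-rest ROC AUCs (classes absent from the truth are
  excluded with a warning; ties count one half), and the 3×3 confusion
  matrix.
- The contribution table reports FL−LL accuracy per client dataset and
  CL−FL on the merged test set; a negative CL−FL means federation beat
  centralization. Deltas are plain differences on the [0, 1] scale.
- Statistical comparisons: stratified five-fold splits, Shapiro–Wilk
  normality (3 ≤ n ≤ 5000, Royston approximation via scipy), and a
  two-sided paired t-test (all-zero differences → t=0, p=1; zero-variance
  nonzero-mean differences → infinite t flagged with p=0).
- Transforms: the full-scale pipeline is random-resized-crop to the input
  size + random horizontal flip + normalization for training, resize-256 +
  center-crop + normalization for testing. A horizontal flip mirrors a
  lateral cephalogram's facing direction and therefore flips the sign
  convention of the anatomy; the flag stays available because the full-scale
  recipe includes it, but synthetic-data runs default to a normalize-only
  pipeline with the flip disabled.

## Synthetic data generator

The generator emulates the two-clinic study structure: client `dicle` (856
images, class ratios 0.46/0.33/0.21, Kim standard) and client `isbi` (400
images, ratios 0.2/0.22/0.58, Steiner standard), 80/20 stratified
train/test. Generation is angle-first: class counts follow deterministic
largest-remainder apportionment of the ratios; an angle is drawn uniformly
from the class's band intersected with ±15°, shrunk 0.1° from each band
boundary so landmark jitter can never cross classes; N and B are placed
(upper-anterior anchor; B below N with an anterior offset proportional to
−angle) and A is solved in closed form so the recomputed signed angle equals
the request to within 1e-9 degrees. Relabeling generated data through the
package's own labeler therefore reproduces the intended class for every
record, at any seed — the generator's central invariant.

Rendering draws a fixed cranial arc, a maxillary ridge through A and a
mandibular polyline through B on a noisy background. Two deliberate signal
choices: the mandible's anterior offset gain is ≈1 px per degree at 64 px
(0.22·size over the 15° clip), and the default landmark jitter is 0.5 px —
the accuracy of careful expert annotation at this crop scale. Together they
keep the angle-coded image signal above the rendering noise, so the classes
are visually learnable by the tiny backbone; away from band boundaries the
classes are cleanly separable, while records near a boundary remain
genuinely hard, as in the real task. What the generator does **not**
emulate: anatomical texture and shape variation, age/sex structure,
scanner/exposure differences, and physical pixel spacing (angles are
scale-invariant, so physical units are ignored). Passing tests on synthetic
data therefore demonstrate the pipeline's correctness and the direction of
the federation effect, not clinical-grade accuracy on real radiographs.

Landmark files are written in the 19-slot layout (A/N/B at lines 5/2/6)
with 16 filler points kept ≥ 5 px from A/N/B — meaningless by design — so
the full annotation-parsing path is exercised.

## Desk-scale study conditions

The test suite and the acceptance script run the default two-client
configuration scaled to ~300 images (205 + 96, preserving the 856:400 ratio
and both ratio rows) at 64×64 on the tiny backbone: 20 epochs for LL/CL and
10 rounds × 5 local epochs for FL, seedable end to end. Under these
conditions, at the suite's fixed seed, centralized training reaches ≥ 0.80
held-out accuracy and the federated model beats both local models on the
merged test set, directionally reproducing the full-scale finding that
federation helps most where a client's local data are small or skewed.
Run-to-run variation across seeds is substantial at this scale (a 60-image
test pool and ~80 optimizer steps), so single-seed accuracies carry a
several-point spread; the small, skewed client's local model trails the
federated model consistently, while the large client's local model can
match it on a favorable draw.

## Known limitations

- The numpy engine is single-threaded CPU code; full-scale 224×224 training
  of the 121-layer configuration is out of its practical range (the
  architecture builds and runs, and checkpoints round-trip, but training at
  that scale calls for a GPU framework).
- Batch-norm statistics are averaged like weights in FedAvg — the simplest
  faithful choice, though not the only defensible one for heterogeneous
  clients.
- Pretrained weights are a loading hook only (`set_parameters` /
  checkpoints); nothing downloads, and all tests run from random
  initialization.
- Secure aggregation, differential privacy and client subsampling are out
  of scope; both clients participate in every round.
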