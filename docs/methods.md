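# Methods

`suturemap` implements a pipeline for classifying sagittal craniosynostosis
(CSO) subtypes — anterior, central, posterior, complex — from CT of infant
skulls. The pipeline has four stages (segmentation, projection,
augmentation, classification) plus a phantom generator that replaces
clinical data with a parametric stand-in. This note records the model
behind each stage, the parameters that matter, and the design decisions
taken where the problem was genuinely open.

## Bone segmentation

CT intensities are in Hounsfield units: air ≈ −1000 HU, brain and scalp
below ~60 HU, cortical bone around +1000 HU. A single global threshold
separates skull from everything else; the default cutoff is **300 HU with a
strict inequality** (a voxel of exactly 300 HU is soft tissue). No
morphological cleanup runs by default — suture gaps are the signal, and
hole-filling would erase them. An optional largest-connected-component
filter can remove disconnected bone (vertebrae, artifacts) before
projection.

## Hemispherical projection

The 3D skull mask is flattened to an N×N binary *suture map*. Each bone
voxel, in physical millimetre coordinates (index × spacing, so anisotropic
slices do not distort angles), is expressed in spherical polar coordinates
(r, θ, φ) about an origin at the **centre of the bottom slice of the
cropped skull bounding box** and mapped to pixel

    m = ⌊θ·cos φ / π · N⌋ + N/2,   n = ⌊θ·sin φ / π · N⌋ + N/2.

With both angles restricted to [−π/2, π/2] this covers a hemisphere only if
θ carries sign. The folding convention: with w = Δz/r and α = atan2(Δy, Δx),
if α ∈ [−π/2, π/2] then φ = α and θ = +arccos w; otherwise φ = α ∓ π and
θ = −arccos w. Algebraically this is the azimuthal-equidistant projection
of the upper hemisphere: the polar axis maps to the image centre, the
equator to the inscribed circle's rim. A pixel is 1 iff at least one bone
voxel maps to it; open sutures therefore appear as 0-valued tracks.

Numerical choices:

- the bracket is `floor` (a `round` option exists; it differs by ≤ 1 pixel);
- indices that land exactly on N (θ = ±π/2) are clamped to N−1 rather than
  dropped, so rim voxels are kept;
- voxels strictly below the origin plane are discarded — the hemisphere is
  all the mapping can represent;
- a voxel exactly at the origin maps to the centre pixel ((r, θ, φ) =
  (0, 0, 0) by convention).

**Sampling density and supersampling.** Voxel centres are point samples; if
the voxel grid is coarse relative to the pixel raster (e.g. 1 mm phantoms
projected at N = 128) the moiré pattern of the lattice leaves unhit pixels
inside solid bone, which read as fake sutures. `project_skull(...,
supersample=s)` splats s³ points per voxel cube instead, which closes these
aliasing holes without widening the true bone footprint. The default
(s = 1, voxel centres) is the reference semantics used by the
oracle-equivalence tests; phantom work uses s = 2. For clinical-resolution
volumes (0.43 mm pixels at N = 512) centre sampling is already dense.

## Augmentation

Each suture map is expanded into exactly **61 deterministic variants**:
3 pure flips, 10 pure rotations (±3…±15° in 3° steps), 6 pure rescales
(0.85…1.15 in 0.05 steps, skipping 1.0), all 30 flip×rotation pairs, and
the 12 horizontal/vertical flip×rescale pairs. The magnitude caps encode a
real failure mode: a large transform can slide the open-suture pattern of
one subtype toward another's. All resampling is nearest-neighbour, so
outputs stay strictly binary; down-scaling zero-pads the border,
up-scaling centre-crops; rotation is about the image centre.

A caveat the numbers make visible: with the projection's axis convention
the antero-posterior axis lies along image *columns*, so a "horizontal"
(column) mirror genuinely swaps anterior and posterior appearance while
keeping the original label. Roughly half the recipe contains such a mirror.
This is deliberate label noise inherited from the protocol being modelled;
it caps blind-test accuracy well below 100 % even on easy phantoms, and it
is one reason anterior/posterior dominate the confusion matrices.

## Phantom generator

The phantom is a stylised infant cranial vault: an ellipsoidal bone shell
(default semi-axes 42 × 55 × 45 mm, 3 mm thick, 1000 HU) over soft tissue
(40 HU) in air (−1000 HU), rendered on a 128³ grid at 1 mm and truncated by
the grid bottom 30 % of the way up the ellipsoid — like a head CT series
that stops at the skull base. (A closed bottom tip would place the
projection origin at a degenerate point and leave the rim unsampled.)
Gaussian HU noise (default σ = 20 HU) is added; at σ ≤ 50 the bone/soft
separation at 300 HU is preserved with overwhelming probability, and the
noiseless phantom segments exactly.

Three great-circle suture bands (default width 3 mm) cross the upper vault:
the midline sagittal band, split into anterior/middle/posterior thirds
along the antero-posterior axis, plus coronal and lambdoid bands. Each
segment has a fused fraction in [0, 1]; the unfused part is carved out of
the shell (set to soft tissue) so it projects as a gap. Subtype presets:

| subtype   | fused segments                  | shape change            |
|-----------|---------------------------------|-------------------------|
| anterior  | anterior sagittal third (0.95)  | AP radius × 1.08        |
| central   | middle third (0.95)             | ridged (shell × 1.6 locally) |
| posterior | posterior sagittal third (0.95) | AP radius × 1.08        |
| complex   | anterior + posterior (0.9), partial coronal/lambdoid | — |

All other segments default to mostly open (fused fraction 0.1–0.6),
matching an infant's unfused sutures. Cohorts jitter radii by ±8 % and
fusion fractions by ±0.08 per phantom, reproducibly from one seed.

What the phantom does *not* emulate: real suture meander and interdigitation,
skull-base anatomy, partial-volume effects, beam hardening, motion. A green
end-to-end test therefore establishes that the pipeline carries a
geometric fusion-pattern signal from voxels to predictions — not clinical
accuracy.

## Classification

The harness follows the transfer-learning contract: a **fixed** feature
extractor and a small trainable head. The shipped backbone
(`TinyConvBackbone`) resizes images to 32², applies 8 seeded zero-mean
random 3×3 convolutions, rectifies, and mean-pools to 512 features; it
never trains, and its checksum is asserted unchanged after fine-tuning. Any
object with the same `transform` surface (e.g. a real pretrained CNN
wrapper) can be substituted. The head is a 64-unit ReLU layer plus a
softmax output; `trainable_scope="head"` trains the output layer only (the
hidden layer stays at its seeded random initialisation, acting as a fixed
random projection), `"all"` trains both dense layers — the
architecture-portable reading of "fine-tune the last two layers".

Training is plain mini-batch gradient descent (batch 32) on the softmax
cross-entropy (natural log), features standardised to train-set mean/SD.
Defaults mirror the reference protocol (learning rate 0.001, 7000 steps,
training accuracy each step, validation accuracy every 10 steps). The
desk-scale end-to-end check instead uses learning rate 0.05 and ≤ 1500
steps — the 0.001 rate is tuned to fine-tuning a large pretrained network,
not to a 64-parameter-per-class softmax head, which at 0.001 simply has not
converged within the step budget. Accuracies are reported as percentages to
two decimals; all randomness (hold-out choice, shuffling, initialisation,
batches) flows from explicit integer seeds.

**Splitting.** A blind hold-out (default 2 cases per subtype) is removed
*before* augmentation and kept un-augmented. The remaining cases are
augmented and split 3:1:1 at image level by default — faithful to the
protocol being modelled, and deliberately leaky, since augments of one case
land in both train and test. `grouped=True` gives the case-level,
leakage-free alternative. Partition sizes use cumulative rounding, so every
part is within ±1 of the exact proportion (grouped splitting is only as
exact as whole cases allow). On the shipped phantoms the leak confers no
measurable advantage — the class signal generalises across cases, so
image-level and grouped accuracies coincide within noise; the leakage is
demonstrated structurally (shared case ids across partitions), not as an
accuracy gap.

`repeated_train` re-splits and re-fits n times (default 30) with derived
seeds and averages the test accuracy, the stabiliser used on small raw
cohorts. `embed_2d` runs t-SNE (PCA init, perplexity ≤ 30 and < n/3) on
last-hidden-layer features for the cluster-structure picture; identical
feature vectors short-circuit to coincident points.

## Annotations

Rater labels live in a case × rater matrix with the four subtypes plus
`unlabeled`. The **overlap rate** is the percentage of cases on which *all*
raters give the same non-unlabeled label (a case everyone leaves unlabeled
is non-concordant); the disagreement rate is its complement, computed from
the same exact fraction so the two always sum to 100. Per-rater ground
truths drop unlabeled cases; the majority vote keeps cases where ≥ 2 raters
agree on a subtype and discards ties. Chance-corrected agreement (κ) is
deliberately out of scope.

## Known limitations

- DICOM series input is recognised but unsupported (no DICOM parser in the
  dependency set); convert to NIfTI first. The NRRD reader is minimal
  (3D, raw/gzip encodings, diagonal space directions).
- The projection is not invertible and not equal-area; pixel counts are a
  proxy for suture area only locally.
- The 61-transform recipe is one documented instantiation of the
  flip/rotate/rescale families; only its count and families are canonical.
- Phantom realism is geometric, not radiological (see above); blind-test
  accuracies on phantoms say nothing about clinical performance.
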