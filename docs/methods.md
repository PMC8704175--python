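# Methods

This note documents the models, conventions and numerical choices
behind `segeval`, and what the synthetic-data experiments do and do not
demonstrate.

## Geometry conventions

Masks are binary voxel grids ordered (z, y, x) with strictly positive
anisotropic spacing (dz, dy, dx) in millimetres. Voxel indices are
0-based and a voxel's physical coordinate is its **center**,
`origin + (i·dz, j·dy, k·dx)`. Planar contours are ordered (y, x)
vertex lists in mm, implicitly closed; rasterization marks a voxel
foreground iff its center is inside a polygon on its slice by the
even-odd rule, with the tie (a center exactly on a vertex) resolved as
inside so results are deterministic. Rasterization is invariant to the
choice of starting vertex.

## Distance metrics

DSC is computed volumetrically over foreground voxel counts. Two empty
masks are an error, not DSC = 1: silently scoring a missing structure
as perfect would hide pipeline failures.

The Hausdorff-percentile family is computed between point sets in 3D
physical mm. The **surface** point set (default) contains the centers
of foreground voxels with at least one 6-connected background or
out-of-grid neighbour; the **full** set contains every foreground
voxel center. Both are exposed because the literature is inconsistent
about which set "the points of A and B" means; the surface convention
is the common choice for HD95 and is the default. Directed distances
use a KD-tree; percentiles interpolate linearly between order
statistics; the symmetric HD95 is the maximum of the two directed 95th
percentiles, which reduces to the classical Hausdorff distance at
q = 100. Note the published definition of "95HD" as a three-way
maximum of h(A,B), h(B,A) and "95th" is not well-formed as written;
it is implemented as the standard HD95 just described, which matches
the metric's name and reported magnitudes.

Cohort summaries report mean ± sample SD (n−1 denominator; a single
patient gets SD 0 by convention), rounded half-up to 2 decimals the way
clinical tables print them. Half-up rounding operates on the shortest
decimal representation so that e.g. 2.675 → 2.68 despite binary
floating point.

### Known erratum in the bundled validation table

The bundled 20-patient validation table reproduces the published
per-patient values verbatim. Its Turing-group 95HD summary row
("8.97 ± 1.86") is inconsistent with the ten values it summarises,
whose mean is 7.64 (the SD 1.86 does match). The whole-cohort mean
8.11 mm is consistent with all 20 values and is the number this
package reproduces; the group mean is reported as recomputed, 7.64.

### Group comparison tests

`mann_whitney` implements the two-sided Mann-Whitney U test: exact
enumeration of all labelings for pooled n ≤ 14 (valid under ties,
two-sided by distance of U from its null mean), and the normal
approximation with tie and continuity corrections otherwise. U is
reported as the smaller directed statistic. Degenerate input (all
values identical) yields p = 1 with a warning.

On the bundled validation table the published group-comparison
p-values (0.113 for DSC, 0.284 for 95HD) are **not** Mann-Whitney
p-values, although the rank-sum test is the one named in the study
protocol: every Mann-Whitney variant (asymptotic with/without tie and
continuity corrections, exact) gives 0.167–0.190 and 0.257–0.273
respectively, while a two-sample Student t test gives 0.11340 and
0.28430 — exactly the printed numbers. The package therefore exposes
`t_test` alongside `mann_whitney`, reports both, and does not bend the
rank-sum implementation toward the printed values. One acceptance-style
regression asserting the rank-sum p equals 0.113 is intentionally left
failing as a record of this discrepancy.

## Weighted-dense-skip U-Net

Backbone: per-level double 3×3 convolution + ReLU blocks, 2×2 max-pool
downsampling, factor-2 bilinear upsampling (half-pixel-center
alignment, clamped edges), classic level-matched encoder-to-decoder
concatenation skips, 1×1 sigmoid head. Channels double per level from
`base_channels`.

Dense connections: within the encoder path and within the decoder path
(decoder nodes = bottleneck plus each decoder block), every ordered
pair of levels i < j gets an extra feed-forward connection — C(depth,2)
per path, e.g. 6 + 6 at depth 4. "Level" is interpreted as a
resolution block, not an individual convolution layer. A connection
average-pools (encoder) or bilinearly upsamples (decoder) the source
block's output to the target scale, projects it to the target block's
input channels with a 1×1 convolution, multiplies by the gate
`sigmoid(w)` with `w` initialised to 0 (gate 0.5), and **adds** it to
the target block's standard input. Addition rather than concatenation
keeps channel counts independent of how many connections survive
pruning. Classic skips are never gated.

Pruning removes connections with gate ≤ τ (default τ = 0.05) from the
forward graph entirely — they are skipped, not multiplied by zero — so
τ = 1 reduces the network bit-exactly to the plain backbone, and kept
sets shrink monotonically in τ. Optional fine-tuning after pruning is
supported by simply calling `fit` again on the pruned model; it is off
by default.

Training: Dice loss + binary cross-entropy with equal weights
(Dice smoothing constant 1, BCE computed from logits for stability),
Adam at learning rate 1e-3, batch size 4 (the CLI benchmark uses 8), a
seeded 90:10 train/validation split, ≥ 50 epochs, and retention of the
checkpoint with the lowest validation loss. All randomness flows from
one `numpy` generator seed, and all operations are deterministic, so a
run reproduces bit-for-bit on one machine. A NaN validation loss
aborts with the loss history in the error.

The network and its reverse-mode autograd are implemented directly on
numpy arrays (im2col + BLAS matmul convolutions; bilinear resampling as
cached dense interpolation matrices so both directions are matmuls).
Analytic gradients are verified against central finite differences in
float64; the check jitters the biases first, because zero-initialised
biases leave some pre-activations exactly at the ReLU kink where finite
differences are one-sided.

Inference is slice-wise: per-slice sigmoid maps thresholded at 0.5,
stacked with the input spacing, and post-processed by keeping the
largest 3D connected component (an empty prediction stays empty).

## Synthetic phantoms

Each phantom slice contains a soft-tissue body ellipse (intensity
0.35), two lateral high-intensity "bone" ellipses (0.9), and a
posterior target blob (0.55) over Gaussian pixel noise (sd 0.04),
clipped to [0, 1]. The target is a radially perturbed ellipse: its
polar radius is the ellipse radial function plus a Gaussian field
smooth and periodic in angle and smooth across slices, with standard
deviation `boundary_noise_sd_mm` (default 1 mm); the volume tapers
toward its first and last slice. The mask is the exact rasterization
of the generating 72-vertex contour. Defaults (64×64 pixels, spacing
3×1×1 mm, mean target radius 9 mm) are desk-scale: large enough for
the network to need multiscale context, small enough to train on one
CPU core in minutes.

`perturb_mask` emulates an imperfect auto-contour: the signed Euclidean
distance to the mask boundary is compared against a smooth Gaussian
random field (≈4 mm correlation length) scaled to a chosen sd in mm, so
the surface moves along its normal by that field. Expected DSC
decreases monotonically with the sd; at ≈2 mm the phantom cohort's
mean DSC lands in 0.85–0.95, the regime reported for clinical CTV
auto-segmentation.

What the phantoms do **not** emulate: Hounsfield-calibrated CT physics,
multi-organ anatomy, ambiguous soft-tissue boundaries, inter-patient
pose variation, or the sample sizes of clinical training sets. Passing
the phantom benchmark (held-out mean DSC ≥ 0.85 after 50 epochs on 40
slices) shows the architecture, loss, training loop and pruning behave
correctly — it does not certify clinical-grade performance, which the
bundled validation table documents for the original full-scale model
(DSC ≈ 0.90 on real CT) and which is out of reach at desk scale.

## Simulated rater studies

Ordinal scoring uses a latent-variable cutpoint model: the latent
rating of contour i by clinician c in session s is
`q_i + b_c + sd_resid · (√ρ·u_ic + √(1−ρ)·e_ics)` with q ~ N(arm mean,
0.35²), b ~ N(0, 0.25²), u, e standard normal and sd_resid = 0.45;
cutpoints (0.5, 1.5, 2.5) map the latent value to the 0–3 rubric
(rejected / major revision / minor revision / accepted). ρ (default
0.6) is the exact between-session correlation on the latent scale and
only approximate after discretisation — a documented limitation. The
default panel (10 clinicians × 50 contours per arm × 2 sessions, arm
means 2.6 vs 2.5) mirrors the published study's structure and effect
size; the closed-form expected mean score
`E[score] = Σ_k P(latent > c_k)` is used as the recovery oracle in
tests.

The Turing test simulator draws, per clinician × slice, a
Gaussian-copula pair of session judgements that are positive (AI
chosen) with probability `turing_positive_prob` (default 0.405, the
published week-0 rate) and correlated ρ across sessions; red/green
colors are re-randomised per slice and session as the blinding
protocol prescribes.

Type-I-error simulations test Mann-Whitney **per clinician** (one
clinician per replicate): ratings of different contours by one
clinician are independent, so the nominal 5% level applies. Pooling
all clinicians' ratings of the same contours would cluster the data
and inflate the error rate — that is a property of the design, not of
the implementation.

## Clinical-evaluation statistics

Per-clinician mean = sum of scores / number rated. The **overall mean
per arm is the unweighted mean of per-clinician means** — the
convention that reproduces the published summary row (2.59/2.52 at
week 0) — and the rating-weighted pooled mean is reported alongside,
since the two differ when clinicians rate unequal numbers.
Acceptability is the percentage of ratings with score ≥ 2, "fully
acceptable" the percentage with score 3. Missing (clinician, arm)
cells are listed and excluded from denominators.

Cohen's kappa between the two sessions is unweighted by default
(linear/quadratic weights by flag), flagged acceptable at κ ≥ 0.2, and
reported as undefined when the chance agreement is 1 (no variation to
agree beyond). McNemar's test on paired per-slice binary judgements
uses the exact binomial when there are fewer than 25 discordant pairs
and the continuity-corrected chi-square otherwise; zero discordance
gives p = 1. Per-clinician AI-vs-GT score comparisons use the
unpaired Mann-Whitney test, since the published per-clinician p-values
do not state a pairing structure and could not be attributed to a
specific paired test; they are treated as non-reproducible.

The Turing intelligence criterion is implemented **inclusively**
(rate ≥ 30% passes): the published study counts a clinician at exactly
30/100 as meeting its "more than 30%" criterion, and the inclusive
reading reproduces that accounting. Both verdict rules — every
clinician passing (default, matching the study's wording) and the mean
rate passing — are reported. Per-slice mean scores across clinicians
are summarised by the counts of slices at ≥ 0.3 and ≥ 0.5.

The bundled score-count and Turing-count tables aggregate away contour
and slice identities, so session-pairing statistics (kappa, McNemar)
cannot be recomputed from them; their expansions into long tables are
marked synthetic in that respect and are used only for distributional
summaries. The published per-clinician kappa and McNemar values would
require the raw paired responses, which are not public.

## Problem sizes and budgets

Tests and the acceptance script run the full pipeline at desk scale:
40 training slices / 10 held-out phantoms / 50 epochs for the network
benchmark (a few minutes on one CPU core), 1000 replicates for the
type-I-error simulation, 50 random mask pairs for the brute-force
metric verification. These sizes were chosen as the smallest at which
each claim is meaningfully exercised.

## Known limitations

- 2D slice-wise network only; no 3D convolutions, GPU support, or
  clinical-capacity configurations.
- DICOM RT-Structure I/O, multi-label structures and registration are
  out of scope (NIfTI, PNG stacks and JSON contours are supported).
- The ordinal-score session correlation is exact only on the latent
  scale.
- The Mann-Whitney asymptotic branch is conservative for small tied
  samples; the exact branch covers pooled n ≤ 14.
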