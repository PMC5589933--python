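# Methods

## Motion model and registration

Consecutive frames of a handheld confocal sweep are related by a
6-parameter affine transform: probe translation dominates, with small
rotation, scale and shear introduced by changes in contact angle and
pressure. The transform is represented as a 3×3 homogeneous matrix *M*
with bottom row (0,0,1), mapping frame-*t* (x, y) coordinates — column,
row, origin at the top-left pixel center — into frame-*t−1* coordinates.
Although 3 point correspondences already determine all 6 parameters
exactly (the minimal RANSAC sample), the full affine is estimated, not a
restricted 3-parameter subfamily: scale and shear are precisely the
quantities the scene-cut detector later inspects.

**Keypoints.** Detection and raw description use the standard SIFT
pipeline via `skimage.feature.SIFT`: 3 scales per octave, initial
σ = 1.6, contrast threshold 0.03 on [0,1] intensities (passed to the
per-level DoG test as 0.03/n_scales), edge-response ratio 10, 36-bin
orientation histogram with secondary peaks ≥ 80% of the maximum spawning
duplicate keypoints, 4×4×8 descriptor with the clamp-at-0.2 and
renormalize step. skimage quantizes descriptors to uint8; the package
restores exact unit ℓ₂ norm so that descriptor distances are scale-free
and a zero distance means identical descriptors. Input upsampling is off
by default (speed); enabling it (`KeypointParams(upsampling=2)`) roughly
doubles keypoint counts at sub-octave scales. On the synthetic texture
the detector returns on the order of 10³–10⁴ keypoints per 1000×1000
frame, matching the density regime reported for real tissue to an order
of magnitude; the exact count on clinical RCM data depends on tissue
texture no synthetic model pins down.

**Matching.** Exact two-nearest-neighbor search over descriptors (dense
BLAS distance matrix; no approximate index), keeping a match only when
second-best/best distance ≥ 1.2. Ties break toward the lower
previous-frame index, making the matcher deterministic and directly
comparable to a brute-force oracle. A previous-frame keypoint may be
claimed by several current-frame keypoints; RANSAC resolves any such
conflicts downstream.

**RANSAC.** 3000 random 3-subsets by default; each candidate affine is
scored by the mean of per-match ℓ₁ reprojection errors truncated at the
inlier tolerance (MSAC-style), so gross outliers saturate instead of
dominating. The tolerance is 50 px ℓ₁, computed as |dx| + |dy|. After
model selection, matches above the tolerance are pruned. Collinear
samples (determinant below 10⁻⁹ relative to the coordinate scale) are
skipped. Sampling is driven by a seeded `numpy` generator; a fixed seed
gives bit-reproducible output.

**Feasibility.** A pair is declared unregistrable — the scene-cut
signal — when fewer than `min_matches` ratio-test matches survive, when
all trials are degenerate, or when fewer than `min_matches` inliers
survive pruning. `min_matches` defaults to 12, four times the minimal
sample: with only a handful of matches, a spurious consensus is easy to
assemble under a 50-px tolerance (observed on zero-overlap frame pairs,
whose few accidental descriptor matches would otherwise register), while
genuinely overlapping textured frames yield dozens to hundreds.

**Penalized refinement.** The final fit over the inliers minimizes

    Σᵢ ‖M pᵢ − qᵢ‖₂ + λ [(a₁₁−1)² + (a₂₂−1)² + a₁₂² + a₂₁²].

The data term is a sum of unsquared ℓ₂ norms (robust to residual-scale
outliers); the penalty pulls the linear block toward the identity and
never touches the translation. By default λ is sized relative to the
problem, λ = n_inliers · frame_side / 500, which keeps the penalty's
share of the data-term gradient roughly constant (~1%): a fixed absolute
weight appropriate for ~500 inliers on 1000-px clinical frames (λ = 10³,
recovered exactly by the formula at that geometry) would overwhelm the
data term on small frames with few inliers and visibly bias genuine scale
changes toward 1 — enough to hide a warp artifact from the scene-cut
rule. Homogeneously spread inliers make the penalty's effect negligible
(≤ 0.1 px corner displacement); spatially clustered inliers are where it
earns its keep, shrinking the extrapolation error at the far corner of
the frame. Optimization: the objective is non-smooth where residuals
vanish, so L-BFGS-B (cap 200 iterations, gradient tolerance 10⁻⁸) is
warm-started at the closed-form ridge solution (same penalty, squared
data term), and the best of {RANSAC init, ridge, polished} under the true
objective is returned. `squared=True` selects the closed-form ridge
variant outright.

## Scene cuts

For each consecutive pair the homogeneous-matrix trace a₁₁ + a₂₂ + 1 is
compared against a threshold, default 3.5; pure translation gives exactly
3. A cut is placed before frame *t* when the trace exceeds the threshold
or when the pair was unregistrable (blur and loss of overlap surface as
infeasibility — no separate blur metric exists). The literal rule fires
only on expansion; an opt-in `symmetric` mode also cuts on the mirrored
contraction condition (trace < 2.5 at default threshold) and on shear
|a₁₂| + |a₂₁| > 0.25, for robustness at the cost of strict fidelity to
the default rule. Segments are maximal runs between cuts; within a
segment, cumulative transforms into the segment's first frame are built
by composition, C_t = C_{t−1}·M_{t−1,t}. Sub-mosaics are not
auto-assembled across cuts — relative placement there is an operator
decision.

## Seam stitching

Frames are warped into segment-reference coordinates by inverse mapping
(`scipy.ndimage.map_coordinates`); the coverage mask is true exactly
where the inverse-mapped location falls inside the source frame. Bilinear
interpolation is the default; nearest-neighbor mode preserves source
values bit-exactly and backs all provenance guarantees.

Each new frame is stitched against the growing composite (sequential
binary stitching, acquisition order; an all-frames multi-label
formulation would forfeit solver exactness for no tested benefit). Within
the overlap, a binary labeling (existing vs incoming) is solved exactly
by max-flow/min-cut on the 4-connected grid: the cost of an edge (p, q)
whose endpoints take different labels is |A(p)−B(p)| + |A(q)−B(q)| — the
photomontage seam energy; a per-pixel intensity-difference unary would be
label-symmetric and cannot move the optimum, so unaries carry only the
hard membership constraints. Overlap pixels bordering existing-only
territory are forced to the existing label (symmetrically for incoming),
implemented as a large finite unary (10⁶ × the maximum pairwise cost in
the float problem; capacity 2³⁰ in the solver). A pixel squeezed between
both territories (only possible in degenerate one-or-two-pixel-wide
overlaps) has its constraints dropped rather than raising an error;
problems whose constraints genuinely conflict are rejected.

**Integer quantization.** `scipy.sparse.csgraph.maximum_flow` requires
int32 capacities. Costs are scaled by 2²⁹ / B, where B is the energy of
the cheapest of three feasible heuristic labelings (all-existing,
all-incoming, flood-from-incoming-boundary) — an upper bound on the
optimal energy — and capacities are clamped at 2²⁹. Clamping cannot
change the argmin: any cut containing a clamped edge already costs ≥ B.
Per-edge rounding error is at most B/2³⁰, so labelings whose energies
differ by more than ~n_edges·B/2³⁰ (≈ 10⁻⁷·B on realistic seams) are
ordered correctly; the returned energy itself is recomputed exactly in
floating point from the chosen assignment. The cut partition is read off
by breadth-first search on the residual graph from the source terminal.

The label map records every covered pixel's source frame; in
nearest-neighbor mode every mosaic pixel equals its labeled frame's pixel
bit-exactly, which the test suite asserts exhaustively on every mosaic it
builds.

## Synthetic data

The virtual tissue plane is smoothed Gaussian noise (correlation length
set by `granularity`, default 8 px) plus Poisson-scattered Gaussian-blob
"nuclei" (~1 per (4·granularity)² px, blob σ = granularity/2), min-max
normalized — enough SIFT-detectable structure at controllable density to
stand in for tissue texture. Sweeps sample the texture under per-frame
affine ground truth along linear, arc, spiral or freehand paths with
additive Gaussian intensity noise (default σ = 0.01) and sub-pixel
translation jitter (default 0.5 px). Injected events mirror clinical
failure modes: `jump` displaces the path by more than a frame (no
overlap), `blur` applies a motion-blur kernel, `warp_spike` multiplies
one frame's true a₁₁ (default magnitude 1.6 in tests, putting the true
pairwise trace at 3.6 — just past the 3.5 threshold, so detection is
tested at its hardest). Everything is deterministic per seed.

What the simulator does **not** reproduce: speckle statistics, depth
sectioning, illumination falloff, lens distortion, tissue deformation,
and real nucleus morphology. Passing tests therefore demonstrate the
pipeline's correctness and robustness under controlled geometry and
noise, not clinical image quality; keypoint densities and match counts on
real RCM video will differ.

## Test and acceptance geometry

Quantitative suites run at desk scale, chosen as the smallest geometry
that still exercises every mechanism: 256×256-px frames, 60-px steps and
50 frames for registration accuracy (matching the simulator's default
noise); 128×128-px frames, 30-px steps, 7-frame sequences for the
100-seed scene-cut recall suite and 5-frame sequences for the 100-seed
false-positive suite; 4×4 seam instances for exhaustive-enumeration
optimality (200 instances) and 64×64 instances against straight-seam
upper bounds. A 1000×1000 frame mode mirrors clinical geometry and is
used for keypoint-density and RANSAC-robustness checks.
`scripts/acceptance.py` recomputes all of these from scratch at reduced
seed counts (30–100 per suite) and reports each measured value with its
problem size.

## Known limitations

- The literal trace rule is blind to contraction and pure shear; the
  symmetric mode covers them but is off by default.
- Sequential binary stitching is order-dependent; a frame's pixels may be
  overwritten by any later overlapping frame.
- Lossy video input is accepted with a warning; compression artifacts
  degrade matching in ways the synthetic suite does not model.
- Cross-cut sub-mosaic assembly is manual by design.
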