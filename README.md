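# confomosaic

Automated video-mosaicking for handheld reflectance confocal microscopy
(RCM).

RCM images skin at cellular resolution, but each video frame covers only a
sub-millimeter field of view — far too small to assess a lesion's margins
the way a dermatopathologist reads a histology slide. When the probe is
swept slowly across the skin while recording video, the frames overlap
heavily, and a much larger composite image can be recovered
computationally. `confomosaic` turns such a frame sequence into
large-field mosaics:

1. **Keypoints** — SIFT difference-of-Gaussian extrema with 128-length
   orientation-normalized gradient-histogram descriptors are detected in
   every frame.
2. **Matching** — each keypoint in frame *t* is paired with its two most
   similar keypoints in frame *t−1* by descriptor ℓ₂ distance; a match is
   kept only when the second-best/best distance ratio is ≥ 1.2 (keypoints
   in repetitive texture are not unique and are discarded).
3. **Registration** — the inter-frame motion is a 6-parameter affine
   *M* (3×3 homogeneous, bottom row (0,0,1)). RANSAC over random 3-match
   subsets (3000 trials) selects the model with the lowest truncated mean
   ℓ₁ generalization error; matches reprojecting worse than 50 px (ℓ₁)
   are pruned; the final fit minimizes
   Σᵢ‖M pᵢ − qᵢ‖₂ + λ[(a₁₁−1)² + (a₂₂−1)² + a₁₂² + a₂₁²],
   a penalty on scale change and shear that prevents over-fitting when the
   surviving matches cluster in one region of the frame.
4. **Scene cuts** — smooth probe motion gives near-pure-translation
   transforms, whose homogeneous trace a₁₁ + a₂₂ + 1 is ideally 3. A cut
   is placed where the trace exceeds 3.5 (warp artifact) or where
   registration is infeasible altogether (motion blur, no overlap). Each
   contiguous run of frames becomes its own sub-mosaic; assembling
   sub-mosaics across cuts is left to the operator.
5. **Stitching** — frames are warped into the segment reference frame and
   composited without any blending: in each overlap a minimum-cut on a
   4-connected grid graph finds the continuous seam minimizing
   Σ |A(p)−B(p)| + |A(q)−B(q)| over label-discontinuity edges, so every
   mosaic pixel keeps the unaltered value of exactly one source frame. A
   per-pixel label map records that provenance.

No patient data is required anywhere: `confomosaic.synthetic` simulates
handheld sweeps over a ground-truthed virtual tissue plane, including the
artifacts (jumps, motion blur, warp spikes) that force scene cuts.

## Worked example

Simulate an 8-frame linear sweep (256×256-px frames advancing 60 px/frame)
and stitch it:

```bash
confomosaic simulate --path linear --frames 8 --frame-size 256 \
    --step 60 --seed 7 --out demo/seq
confomosaic stitch --input demo/seq --output demo/out --seed 7
```

which prints

```
wrote 8 frames and ground_truth.json to demo/seq
read 8 frames from demo/seq
segment [0, 7] -> mosaic_00000_00007.tif (258x676)
1 segment(s), cuts at none; report written to demo/out/run_report.json
```

The mosaic is 258×676 px — eight 256-px frames stepping 60 px span
256 + 7·60 = 676 columns — and no scene cut fired because the simulated
motion is smooth. `run_report.json` holds the per-pair diagnostics; the
first frame pair reads

```
pair [0, 1]  matches 416  inliers 412  trace 2.9999
affine params [1.0, -0.0, 59.865, -0.0, 1.0, -0.544]
```

i.e. the recovered transform is a near-pure translation of ~60 px
(trace ≈ 3, the pure-translation ideal), matching the simulated step
within the sub-pixel jitter the simulator injects. The companion
`mosaic_*_labels.tif` stores each pixel's source-frame index (−1 where no
frame reached the canvas).

Library use mirrors the CLI:

```python
import confomosaic as cm

frames, meta = cm.read_sequence("demo/seq")
result = cm.build_mosaics(frames, cm.PipelineParams(seed=7))
result.cuts            # scene-cut positions, [] here
result.mosaics[0]      # Canvas: .pixels, .label_map, .offset
```

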