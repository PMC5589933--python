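"""End-to-end video-mosaicking pipeline.

Orchestrates the stages in acquisition order: per-frame keypoint
detection, consecutive-frame descriptor matching with the ratio test,
RANSAC affine estimation with 50-px l1 pruning and the penalized final
fit, trace-based scene-cut detection, segmentation, and per-segment
graph-cut stitching.  Returns all segment mosaics plus a run report
(transforms, inlier counts, cut positions, timings) suitable for JSON
serialization.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_frames import Frame
from .keypoints import KeypointParams, detect_keypoints
from .matching import DEFAULT_RATIO_THRESHOLD, match_coordinates, match_frames
from .registration import (
    DEFAULT_INLIER_TOL,
    DEFAULT_N_TRIALS,
    AffineTransform,
    RegistrationInfeasible,
    ransac_affine,
    refine_affine_penalized,
)
from .scene_cut import (
    DEFAULT_TRACE_THRESHOLD,
    SubvideoSegment,
    detect_cuts,
    segment_sequence,
)
from .stitching import Canvas, composite_segment

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All tunable pipeline settings in one place."""

    keypoints: KeypointParams = field(default_factory=KeypointParams)
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    ransac_trials: int = DEFAULT_N_TRIALS
    inlier_tol: float = DEFAULT_INLIER_TOL
    lambda_reg: float | None = None  # None -> auto-scaled (see registration)
    trace_threshold: float = DEFAULT_TRACE_THRESHOLD
    symmetric_cuts: bool = False
    warp_mode: str = "bilinear"
    seed: int = 0
    min_matches: int = 12  # 4x the minimal sample; below this the pair is infeasible


@dataclass
class MosaicResult:
    """Pipeline output: mosaics, segmentation, and diagnostics."""

    segments: list[SubvideoSegment]
    mosaics: list[Canvas]
    pairwise_transforms: list[Optional[AffineTransform]]
    cuts: list[int]
    report: dict


def register_sequence(
    frames: list[Frame], params: PipelineParams | None = None
) -> tuple[list[Optional[AffineTransform]], dict]:
    """Estimate the affine for every consecutive frame pair.

    Returns one entry per pair: the refined transform, or ``None`` when
    registration is infeasible (too few keypoints or matches — the scene
    cut signal).  The report dict carries per-pair diagnostics.
    """
    params = params or PipelineParams()
    rng = np.random.default_rng(params.seed)
    t0 = time.perf_counter()

    keypoints = [detect_keypoints(f, params.keypoints) for f in frames]
    t_kp = time.perf_counter() - t0

    transforms: list[Optional[AffineTransform]] = []
    pair_reports = []
    for t in range(1, len(frames)):
        kps_prev, kps_curr = keypoints[t - 1], keypoints[t]
        entry: dict = {"pair": [t - 1, t]}
        tf: Optional[AffineTransform] = None
        try:
            if len(kps_prev) < 2 or not kps_curr:
                raise RegistrationInfeasible(
                    f"too few keypoints ({len(kps_prev)} prev, "
                    f"{len(kps_curr)} curr)"
                )
            matches = match_frames(kps_prev, kps_curr, params.ratio_threshold)
            entry["n_matches"] = len(matches)
            if len(matches) < params.min_matches:
                raise RegistrationInfeasible(
                    f"only {len(matches)} ratio-test matches"
                )
            curr, prev = match_coordinates(matches, kps_prev, kps_curr)
            result = ransac_affine(
                curr, prev,
                n_trials=params.ransac_trials,
                inlier_tol=params.inlier_tol,
                seed=rng,
                frame_shape=frames[t].pixels.shape,
            )
            inl = result.inlier_indices
            if inl.size < params.min_matches:
                raise RegistrationInfeasible(
                    f"only {inl.size} inliers survive pruning"
                )
            tf = refine_affine_penalized(
                curr[inl], prev[inl], result.transform,
                lambda_reg=params.lambda_reg,
                frame_shape=frames[t].pixels.shape,
            )
            entry.update(
                n_inliers=int(inl.size),
                mean_residual=result.mean_residual,
                spatial_spread=result.spatial_spread,
                affine_params=tf.params.tolist(),
                trace=tf.trace,
            )
        except RegistrationInfeasible as exc:
            logger.info("pair (%d, %d) infeasible: %s", t - 1, t, exc)
            entry["infeasible"] = str(exc)
        transforms.append(tf)
        pair_reports.append(entry)

    report = {
        "n_frames": len(frames),
        "n_keypoints": [len(k) for k in keypoints],
        "pairs": pair_reports,
        "timing": {
            "keypoints_s": t_kp,
            "registration_s": time.perf_counter() - t0 - t_kp,
        },
        "seed": params.seed,
    }
    return transforms, report


def build_mosaics(
    frames: list[Frame], params: PipelineParams | None = None
) -> MosaicResult:
    """Run the full pipeline: register, cut, segment, stitch."""
    params = params or PipelineParams()
    transforms, report = register_sequence(frames, params)
    cuts = detect_cuts(
        transforms,
        trace_threshold=params.trace_threshold,
        symmetric=params.symmetric_cuts,
    )
    segments = segment_sequence(len(frames), cuts, transforms)
    t0 = time.perf_counter()
    mosaics = [
        composite_segment(seg, frames, warp_mode=params.warp_mode)
        for seg in segments
    ]
    report["cuts"] = cuts
    report["segments"] = [
        {"start": s.start_index, "end": s.end_index} for s in segments
    ]
    report["timing"]["stitching_s"] = time.perf_counter() - t0
    return MosaicResult(
        segments=segments,
        mosaics=mosaics,
        pairwise_transforms=transforms,
        cuts=cuts,
        report=report,
    )
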