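"""Scene-cut detection and sequence segmentation.

Registration artifacts — motion blur, lack of overlap after abrupt probe
motion, strong warp from pressure changes — would smear a mosaic if the
offending frame pair were stitched.  The detector inspects each pairwise
affine: for smooth motion the transform is near a pure translation and the
trace of its homogeneous matrix (a11 + a22 + 1) is close to 3.  A cut is
placed before frame t when the trace exceeds a threshold (default 3.5) or
when registration for the pair was infeasible altogether (too few matches,
e.g. a blurred or non-overlapping frame).  Each maximal run of frames
between cuts is mosaicked separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .registration import AffineTransform

logger = logging.getLogger(__name__)

DEFAULT_TRACE_THRESHOLD = 3.5
IDEAL_TRACE = 3.0  # trace of a pure translation
DEFAULT_SHEAR_THRESHOLD = 0.25  # symmetric mode only


@dataclass
class SubvideoSegment:
    """A maximal run of frames between scene cuts.

    ``cumulative_transforms[i]`` maps frame ``start_index + i`` into the
    segment's reference frame (its first frame, whose entry is the
    identity).  Indices are inclusive at both ends.
    """

    start_index: int
    end_index: int
    cumulative_transforms: list[AffineTransform]

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must not exceed end_index")
        if len(self.cumulative_transforms) != self.n_frames:
            raise ValueError(
                "need one cumulative transform per frame in the segment"
            )

    @property
    def n_frames(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def frame_indices(self) -> range:
        return range(self.start_index, self.end_index + 1)


def detect_cuts(
    transforms: Sequence[Optional[AffineTransform]],
    trace_threshold: float = DEFAULT_TRACE_THRESHOLD,
    symmetric: bool = False,
    shear_threshold: float = DEFAULT_SHEAR_THRESHOLD,
) -> list[int]:
    """Locate scene cuts from pairwise transforms.

    Parameters
    ----------
    transforms : sequence
        Entry ``t`` is the affine for frame pair ``(t, t+1)``, or ``None``
        when registration was infeasible for that pair.
    trace_threshold : float
        Cut when the homogeneous-matrix trace exceeds this (ideal value is
        3 for a pure translation).
    symmetric : bool
        Optional stricter mode: additionally cut on the mirrored
        contraction condition ``trace < 3 - (trace_threshold - 3)`` and on
        shear ``|a12| + |a21| > shear_threshold``.  The default criterion
        is the plain trace rule.

    Returns
    -------
    list of int
        Sorted cut positions; a cut at position ``t`` separates frame
        ``t - 1`` from frame ``t`` (positions are in ``1..n_frames-1``).
    """
    cuts: list[int] = []
    for t, tf in enumerate(transforms, start=1):
        if tf is None:
            cuts.append(t)
            continue
        tr = tf.trace
        if tr > trace_threshold:
            cuts.append(t)
        elif symmetric:
            if tr < IDEAL_TRACE - (trace_threshold - IDEAL_TRACE):
                cuts.append(t)
            elif abs(tf.M[0, 1]) + abs(tf.M[1, 0]) > shear_threshold:
                cuts.append(t)
    return cuts


def segment_sequence(
    n_frames: int,
    cuts: Sequence[int],
    pairwise: Sequence[Optional[AffineTransform]],
) -> list[SubvideoSegment]:
    """Split the sequence at the cuts and accumulate per-segment transforms.

    Within a segment, frame t's cumulative transform is the composition of
    the pairwise transforms back to the segment's first frame:
    ``C[t] = C[t-1] . M_{t-1,t}``.

    Segments partition ``0..n_frames-1`` exactly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if len(pairwise) != n_frames - 1:
        raise ValueError(
            f"expected {n_frames - 1} pairwise transforms, got {len(pairwise)}"
        )
    cuts = list(cuts)
    if cuts != sorted(set(cuts)):
        raise ValueError("cut list must be sorted and duplicate-free")
    if any(c < 1 or c >= n_frames for c in cuts):
        raise ValueError(f"cut positions must lie in 1..{n_frames - 1}")

    boundaries = [0, *cuts, n_frames]
    segments: list[SubvideoSegment] = []
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        cumulative = [AffineTransform.identity()]
        for t in range(start + 1, stop):
            m = pairwise[t - 1]
            if m is None:
                raise ValueError(
                    f"pair ({t - 1}, {t}) is infeasible but no cut separates it"
                )
            cumulative.append(cumulative[-1].compose(m))
        segments.append(
            SubvideoSegment(
                start_index=start,
                end_index=stop - 1,
                cumulative_transforms=cumulative,
            )
        )
    return segments
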