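"""Descriptor matching between consecutive frames with the ratio test.

Every keypoint of the current frame is provisionally paired with its two
most similar previous-frame keypoints by descriptor l2 distance.  A match
is unreliable when those two candidates are nearly equally similar — the
keypoint sits in repeating texture and is not unique — so it is kept only
when ``second_best / best >= ratio_threshold`` (default 1.2).

Matching is exact (dense distance matrix, BLAS-backed); nearest-neighbor
ties break toward the lower previous-frame index for determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .keypoints import Keypoint, descriptor_matrix

logger = logging.getLogger(__name__)

DEFAULT_RATIO_THRESHOLD = 1.2


@dataclass(frozen=True)
class Match:
    """A retained correspondence: current-frame keypoint -> previous-frame.

    ``ratio`` is second-best distance over best distance (>= 1; infinity
    when the best distance is exactly zero and the second-best is not).
    """

    query_index: int
    train_index: int
    distance: float
    ratio: float


def _pairwise_sq_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared l2 distances between rows of a (n, d) and b (m, d)."""
    aa = np.sum(a * a, axis=1)[:, None]
    bb = np.sum(b * b, axis=1)[None, :]
    sq = aa + bb - 2.0 * (a @ b.T)
    np.maximum(sq, 0.0, out=sq)
    return sq


def match_frames(
    kps_prev: list[Keypoint],
    kps_curr: list[Keypoint],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> list[Match]:
    """Match current-frame keypoints against the previous frame.

    Parameters
    ----------
    kps_prev, kps_curr : lists of Keypoint
        Previous and current frame keypoints (both non-empty).
    ratio_threshold : float
        Matches with ``second_best / best`` below this are discarded as
        non-unique.  Must exceed 1.

    Returns
    -------
    list of Match
        One retained match per sufficiently unique current-frame keypoint,
        pairing it with its single best previous-frame neighbor.
    """
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must exceed 1")
    if not kps_prev or not kps_curr:
        raise ValueError("both keypoint lists must be non-empty")
    if len(kps_prev) < 2:
        logger.warning(
            "previous frame has %d keypoint(s); the two-nearest-neighbor "
            "ratio is undefined, rejecting all candidate matches",
            len(kps_prev),
        )
        return []

    d_prev = descriptor_matrix(kps_prev)
    d_curr = descriptor_matrix(kps_curr)
    sq = _pairwise_sq_distances(d_curr, d_prev)

    # lowest index wins ties: argmin is first-occurrence, and the runner-up
    # is re-derived the same way after masking the winner out
    best_idx = np.argmin(sq, axis=1)
    rows = np.arange(sq.shape[0])
    best_sq = sq[rows, best_idx].copy()
    sq[rows, best_idx] = np.inf
    second_sq = sq[rows, np.argmin(sq, axis=1)]

    # recompute the winning distances directly: the inner-product expansion
    # used for the full matrix carries ~1e-7 noise, and the best distance is
    # part of the reported match (must be exactly 0 for identical descriptors)
    best = np.linalg.norm(d_curr - d_prev[best_idx], axis=1)
    second = np.sqrt(second_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(best > 0, second / best, np.where(second > 0, np.inf, 1.0))

    matches = [
        Match(
            query_index=int(q),
            train_index=int(best_idx[q]),
            distance=float(best[q]),
            ratio=float(ratio[q]),
        )
        for q in rows[ratio >= ratio_threshold]
    ]
    return matches


def match_coordinates(
    matches: list[Match], kps_prev: list[Keypoint], kps_curr: list[Keypoint]
) -> tuple[np.ndarray, np.ndarray]:
    """(n, 2) arrays of current-frame and previous-frame match positions."""
    curr = np.array([[kps_curr[m.query_index].x, kps_curr[m.query_index].y]
                     for m in matches]).reshape(-1, 2)
    prev = np.array([[kps_prev[m.train_index].x, kps_prev[m.train_index].y]
                     for m in matches]).reshape(-1, 2)
    return curr, prev
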