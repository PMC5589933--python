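"""Scale-space keypoint detection and 128-length SIFT descriptors.

Handheld confocal video frames change slightly in scale, orientation and
intensity between consecutive frames as probe-to-skin contact varies, so
inter-frame correspondences are anchored on SIFT keypoints: extrema of a
difference-of-Gaussian (DoG) pyramid, each carrying a 4x4-cell x 8-bin
gradient-orientation histogram (128 values) rotated into the keypoint's
dominant gradient direction and Euclidean-normalized.

Detection and raw description are delegated to ``skimage.feature.SIFT``;
this module owns the contract the rest of the pipeline relies on: (x, y)
sub-pixel positions in column/row order, exactly 128 descriptor entries per
keypoint, and unit-norm descriptors comparable by l2 distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT

from .io_frames import Frame

logger = logging.getLogger(__name__)

DESCRIPTOR_LENGTH = 128

#: Minimum frame side length accepted by the detector.
MIN_FRAME_SIDE = 32


@dataclass(frozen=True)
class Keypoint:
    """A scale-space keypoint with its orientation-normalized descriptor.

    ``x`` and ``y`` are sub-pixel frame coordinates (column, row); ``scale``
    is the detection scale in pixels; ``orientation`` the dominant gradient
    direction in radians; ``descriptor`` a unit-norm float vector of length
    128 (all-zero only for pathological gradient-free patches).
    """

    x: float
    y: float
    scale: float
    orientation: float
    descriptor: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.descriptor, dtype=np.float64)
        if d.shape != (DESCRIPTOR_LENGTH,):
            raise ValueError(
                f"descriptor must have length {DESCRIPTOR_LENGTH}, got {d.shape}"
            )
        object.__setattr__(self, "descriptor", d)


@dataclass
class KeypointParams:
    """Detector/descriptor settings (standard published SIFT defaults).

    ``contrast_threshold`` applies to [0, 1] intensities and is divided by
    ``n_scales`` for the per-level DoG test, following the usual convention;
    ``edge_ratio`` rejects edge-like responses by principal-curvature ratio;
    secondary orientation peaks at >= ``orientation_peak_ratio`` of the
    maximum spawn duplicate keypoints; descriptor entries are clamped at
    ``descriptor_clamp`` before renormalization.
    """

    n_scales: int = 3
    sigma_min: float = 1.6
    contrast_threshold: float = 0.03
    edge_ratio: float = 10.0
    n_orientation_bins: int = 36
    orientation_peak_ratio: float = 0.8
    descriptor_clamp: float = 0.2
    upsampling: int = 1  # 2 doubles resolution first (Lowe); 1 is faster


def _make_detector(params: KeypointParams) -> SIFT:
    return SIFT(
        upsampling=params.upsampling,
        n_scales=params.n_scales,
        sigma_min=params.sigma_min,
        c_dog=params.contrast_threshold / params.n_scales,
        c_edge=params.edge_ratio,
        n_bins=params.n_orientation_bins,
        c_max=params.orientation_peak_ratio,
        lambda_descr=6.0,
        n_hist=4,
        n_ori=8,
    )


def detect_keypoints(
    frame: Frame, params: KeypointParams | None = None
) -> list[Keypoint]:
    """Detect DoG keypoints and compute their 128-length descriptors.

    Returns an empty list for frames with no scale-space extrema (e.g. a
    constant image).  Raises ``ValueError`` for frames smaller than
    32x32 pixels.
    """
    params = params or KeypointParams()
    if frame.height < MIN_FRAME_SIDE or frame.width < MIN_FRAME_SIDE:
        raise ValueError(
            f"frame {frame.index} is {frame.height}x{frame.width}; the "
            f"detector requires at least {MIN_FRAME_SIDE}x{MIN_FRAME_SIDE}"
        )
    det = _make_detector(params)
    try:
        det.detect_and_extract(frame.pixels)
    except RuntimeError:
        # skimage raises when the DoG pyramid holds no admissible extrema
        return []

    positions = det.positions  # (row, col) sub-pixel
    descriptors = det.descriptors.astype(np.float64)
    # skimage applies the clamp-and-renormalize step then quantizes to uint8;
    # restore exact unit l2 norm so distances are scale-free.
    norms = np.linalg.norm(descriptors, axis=1, keepdims=True)
    np.divide(descriptors, norms, out=descriptors, where=norms > 0)

    kps: list[Keypoint] = []
    for (row, col), sigma, ori, desc in zip(
        positions, det.sigmas, det.orientations, descriptors
    ):
        # descriptor windows extending past the frame are rejected upstream;
        # clip sub-pixel refinement overshoot to the valid coordinate range
        x = float(np.clip(col, 0, frame.width - 1e-9))
        y = float(np.clip(row, 0, frame.height - 1e-9))
        kps.append(
            Keypoint(x=x, y=y, scale=float(sigma), orientation=float(ori),
                     descriptor=desc)
        )
    return kps


def descriptor_distance(a: Keypoint, b: Keypoint) -> float:
    """Euclidean (l2) distance between two keypoint descriptors."""
    da, db = a.descriptor, b.descriptor
    if da.shape != db.shape:
        raise ValueError("descriptor length mismatch")
    return float(np.linalg.norm(da - db))


def keypoint_coordinates(kps: list[Keypoint]) -> np.ndarray:
    """(n, 2) array of (x, y) positions."""
    if not kps:
        return np.empty((0, 2))
    return np.array([[k.x, k.y] for k in kps])


def descriptor_matrix(kps: list[Keypoint]) -> np.ndarray:
    """(n, 128) array of descriptors."""
    if not kps:
        return np.empty((0, DESCRIPTOR_LENGTH))
    return np.stack([k.descriptor for k in kps])
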