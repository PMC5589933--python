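"""Ground-truthed synthetic acquisition sequences.

Real handheld confocal video cannot ship with the package, so quantitative
tests run on simulated sweeps over a virtual tissue plane: a band-limited
random field seeded with bright cell-nucleus-like blobs, sampled frame by
frame along a camera path with known per-frame affine ground truth.
Acquisition artifacts can be injected on demand — jumps that destroy
inter-frame overlap, motion blur, and warp spikes that scale one frame —
mirroring the failure modes that force scene cuts in clinical footage.

Default geometry is 256x256-pixel frames (a fast stand-in for the
~1000x1000 clinical frame size, which remains available via
``frame_size=1000``) advancing ~60 px/frame, with additive Gaussian
intensity noise (sigma 0.01) and sub-pixel translation jitter (0.5 px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_frames import Frame
from .registration import AffineTransform

DEFAULT_FRAME_SIZE = 256
DEFAULT_STEP = 60.0
DEFAULT_INTENSITY_SIGMA = 0.01
DEFAULT_JITTER_PX = 0.5

EVENT_KINDS = ("jump", "blur", "warp_spike")


@dataclass(frozen=True)
class InjectedEvent:
    """An acquisition artifact at one frame.

    kind "jump": the probe displaces by ``magnitude`` pixels before this
    frame (no overlap with the previous frame when magnitude > frame size);
    "blur": the frame is convolved with a horizontal motion-blur kernel of
    ``magnitude`` pixels; "warp_spike": the frame's true a11 is multiplied
    by ``magnitude`` (pressure-induced stretch).
    """

    frame_index: int
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class PathSpec:
    """Camera path over the texture plane."""

    kind: str = "linear"  # linear | arc | spiral | freehand
    frame_size: int = DEFAULT_FRAME_SIZE
    step: float = DEFAULT_STEP  # px advanced per frame along the path
    rotation_rate: float = 0.0  # rad/frame
    intensity_sigma: float = DEFAULT_INTENSITY_SIGMA
    jitter_px: float = DEFAULT_JITTER_PX


@dataclass
class GroundTruth:
    """What the simulator actually did.

    ``true_transforms[t]`` maps frame-t coordinates into texture
    coordinates; pairwise frame-to-frame truth follows as
    ``inv(T_{t-1}) . T_t``.
    """

    texture: np.ndarray
    true_transforms: list[AffineTransform]
    injected_events: list[InjectedEvent]

    def pairwise_transform(self, t: int) -> AffineTransform:
        """Ground-truth affine mapping frame t into frame t-1."""
        return self.true_transforms[t - 1].inverse().compose(
            self.true_transforms[t]
        )


def make_texture(size: int, seed: int, granularity: float = 8.0) -> np.ndarray:
    """Virtual tissue plane: smoothed noise plus scattered bright blobs.

    ``granularity`` sets the correlation length (pixels) of the field and
    the size of the nucleus-like blobs.  Deterministic per seed; values
    normalized to span [0, 1].
    """
    if size < 512:
        raise ValueError("texture size must be at least 512 pixels")
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(
        rng.standard_normal((size, size)), sigma=granularity / 3.0
    )

    # Poisson-scattered Gaussian blobs, ~1 nucleus per (4*granularity)^2 px
    n_blobs = rng.poisson(size * size / (4.0 * granularity) ** 2)
    blobs = np.zeros((size, size))
    ys = rng.integers(0, size, n_blobs)
    xs = rng.integers(0, size, n_blobs)
    amps = rng.uniform(0.5, 1.0, n_blobs)
    np.add.at(blobs, (ys, xs), amps)
    blobs = ndimage.gaussian_filter(blobs, sigma=granularity / 2.0)
    if blobs.max() > 0:
        blobs /= blobs.max()

    tex = base / max(np.abs(base).max(), 1e-12) + 1.2 * blobs
    tex -= tex.min()
    tex /= tex.max()
    return tex


def _path_positions(
    kind: str, n_frames: int, step: float, start: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    t = np.arange(n_frames, dtype=np.float64)
    if kind == "linear":
        pos = start + np.column_stack([step * t, np.zeros(n_frames)])
    elif kind == "arc":
        radius = step * n_frames / (0.5 * math.pi)
        theta = step * t / radius
        pos = start + radius * np.column_stack(
            [np.sin(theta), 1.0 - np.cos(theta)]
        )
    elif kind == "spiral":
        # archimedean spiral with approximately constant arc-length step
        b = step / (2.0 * math.pi) * 4.0
        theta = np.zeros(n_frames)
        for i in range(1, n_frames):
            r = max(b * theta[i - 1], step / 2.0)
            theta[i] = theta[i - 1] + step / r
        r = b * theta
        pos = start + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        pos -= pos[0] - start
    elif kind == "freehand":
        # smooth random walk: integrated heading noise
        heading = np.cumsum(rng.normal(0.0, 0.15, n_frames))
        steps = np.column_stack([np.cos(heading), np.sin(heading)]) * step
        pos = start + np.vstack([np.zeros(2), np.cumsum(steps[:-1], axis=0)])
    else:
        raise ValueError(f"unknown path kind {kind!r}")
    return pos


def simulate_sweep(
    texture: np.ndarray,
    path_spec: PathSpec | None = None,
    n_frames: int = 50,
    events: Sequence[InjectedEvent] = (),
    seed: int = 0,
) -> tuple[list[Frame], GroundTruth]:
    """Render a frame sequence along a camera path over the texture.

    Each frame samples the texture under its ground-truth affine (bilinear
    interpolation) plus i.i.d. Gaussian intensity noise.  Raises a
    validation error if any frame's footprint leaves the texture.
    """
    spec = path_spec or PathSpec()
    rng = np.random.default_rng(seed)
    events = sorted(events, key=lambda e: e.frame_index)
    fs = spec.frame_size
    # integer margin keeps noiseless integer-step paths on the pixel lattice
    margin = float(round(fs * 1.2))

    start = np.array([margin, margin])
    pos = _path_positions(spec.kind, n_frames, spec.step, start, rng)
    if spec.jitter_px > 0:
        pos = pos + rng.normal(0.0, spec.jitter_px, pos.shape)

    # events modify the path/per-frame transforms
    jump_offset = np.zeros(2)
    offsets = np.zeros_like(pos)
    scale_x = np.ones(n_frames)
    blur_len = np.zeros(n_frames)
    for ev in events:
        if ev.frame_index >= n_frames:
            raise ValueError("event frame index beyond sequence length")
        if ev.kind == "jump":
            jump = np.array([0.0, ev.magnitude])  # perpendicular to the sweep
            jump_offset = jump_offset + jump
            offsets[ev.frame_index:] += jump
        elif ev.kind == "warp_spike":
            scale_x[ev.frame_index] = ev.magnitude
        elif ev.kind == "blur":
            blur_len[ev.frame_index] = ev.magnitude
    pos = pos + offsets

    transforms: list[AffineTransform] = []
    frames: list[Frame] = []
    th, tw = texture.shape
    rows, cols = np.meshgrid(
        np.arange(fs, dtype=np.float64), np.arange(fs, dtype=np.float64),
        indexing="ij",
    )
    for t in range(n_frames):
        angle = spec.rotation_rate * t
        c, s = math.cos(angle), math.sin(angle)
        tf = AffineTransform.from_params(
            scale_x[t] * c, -s, pos[t, 0], scale_x[t] * s, c, pos[t, 1]
        )
        corners = tf.apply(np.array(
            [[0, 0], [fs - 1, 0], [0, fs - 1], [fs - 1, fs - 1]], float
        ))
        if (corners[:, 0].min() < 0 or corners[:, 1].min() < 0
                or corners[:, 0].max() > tw - 1 or corners[:, 1].max() > th - 1):
            raise ValueError(f"frame {t}: camera path exits the texture")
        A, tr = tf.M[:2, :2], tf.M[:2, 2]
        sx = A[0, 0] * cols + A[0, 1] * rows + tr[0]
        sy = A[1, 0] * cols + A[1, 1] * rows + tr[1]
        img = ndimage.map_coordinates(texture, [sy, sx], order=1)
        if blur_len[t] >= 2:
            kernel = np.ones((1, int(blur_len[t]))) / int(blur_len[t])
            img = ndimage.convolve(img, kernel, mode="nearest")
        if spec.intensity_sigma > 0:
            img = img + rng.normal(0.0, spec.intensity_sigma, img.shape)
        frames.append(Frame(index=t, pixels=np.clip(img, 0.0, 1.0)))
        transforms.append(tf)

    truth = GroundTruth(
        texture=texture,
        true_transforms=transforms,
        injected_events=list(events),
    )
    return frames, truth


def make_correspondences(
    true_transform: AffineTransform,
    n_inliers: int,
    n_outliers: int = 0,
    noise_px: float = 0.0,
    frame_shape: tuple[int, int] = (DEFAULT_FRAME_SIZE, DEFAULT_FRAME_SIZE),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic match coordinates for registration tests.

    Draws ``n_inliers`` current-frame points uniformly over the frame and
    maps them through the ground-truth transform (plus optional Gaussian
    position noise) into the previous frame; appends ``n_outliers``
    uniform-random bogus correspondences.  Returns ``(curr, prev)`` arrays.
    """
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    curr = rng.uniform([0, 0], [w - 1, h - 1], size=(n_inliers, 2))
    prev = true_transform.apply(curr)
    if noise_px > 0:
        prev = prev + rng.normal(0.0, noise_px, prev.shape)
    if n_outliers:
        curr_o = rng.uniform([0, 0], [w - 1, h - 1], size=(n_outliers, 2))
        prev_o = rng.uniform([0, 0], [w - 1, h - 1], size=(n_outliers, 2))
        curr = np.vstack([curr, curr_o])
        prev = np.vstack([prev, prev_o])
    return curr, prev
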