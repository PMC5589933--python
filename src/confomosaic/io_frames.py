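"""Frame-sequence input and mosaic output.

Reads grayscale video frames from an image directory (lexicographic order),
a multi-page TIFF stack, or a video container, normalizes intensities to
floating point in [0, 1], and writes mosaics plus per-pixel provenance
(label) maps.

Coordinate convention used throughout the package: row-major arrays,
0-based indices, ``(x, y) = (column, row)`` with the origin at the center
of the top-left pixel.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

logger = logging.getLogger(__name__)

#: Label-map value for canvas pixels not covered by any frame.
UNCOVERED = -1

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
_VIDEO_EXTENSIONS = {".avi", ".mp4", ".mov", ".mkv", ".wmv"}
_LOSSY_EXTENSIONS = {".jpg", ".jpeg"} | _VIDEO_EXTENSIONS


class SequenceValidationError(ValueError):
    """Raised when a frame sequence violates a structural invariant."""


@dataclass(frozen=True)
class Frame:
    """One grayscale video frame.

    Attributes
    ----------
    index : int
        0-based position in the acquisition sequence.
    pixels : ndarray
        2-D float array of intensities in [0, 1].
    """

    index: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise SequenceValidationError(
                f"frame {self.index}: pixels must be a non-empty 2-D array, "
                f"got shape {px.shape}"
            )
        if self.index < 0:
            raise SequenceValidationError(f"frame index must be >= 0, got {self.index}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SequenceMeta:
    """Bookkeeping for a loaded frame sequence."""

    n_frames: int
    frame_rate: float = 7.0
    source_path: str = ""
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SequenceValidationError("a sequence must contain at least one frame")


def normalize_intensities(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Map raw pixel data linearly onto float64 [0, 1].

    Integer input of ``b`` bits maps ``[0, 2**b - 1] -> [0, 1]``; floating
    input is assumed already in [0, 1] and is only clipped.  Returns the
    normalized array and the inferred source bit depth.
    """
    raw = np.asarray(raw)
    if raw.ndim == 3:  # incidental color input: RCM is natively single-channel
        raw = raw.astype(np.float64).mean(axis=2)
        return np.clip(raw / 255.0, 0.0, 1.0), 8
    if np.issubdtype(raw.dtype, np.integer):
        bit_depth = raw.dtype.itemsize * 8
        scale = float(2**bit_depth - 1)
        return raw.astype(np.float64) / scale, bit_depth
    return np.clip(raw.astype(np.float64), 0.0, 1.0), 32


def _to_gray(raw: np.ndarray) -> np.ndarray:
    if raw.ndim == 3:
        return raw.astype(np.float64).mean(axis=2)
    return raw


def _infer_kind(path: Path) -> str:
    if path.is_dir():
        return "image_dir"
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "tiff_stack"
    if suffix in _VIDEO_EXTENSIONS:
        return "video"
    raise SequenceValidationError(f"cannot infer sequence kind for {path}")


def read_sequence(
    path: str | os.PathLike, kind: str = "auto"
) -> tuple[list[Frame], SequenceMeta]:
    """Read a frame sequence from disk.

    Parameters
    ----------
    path : path-like
        Image directory, multi-page TIFF, or video file.
    kind : {"auto", "image_dir", "tiff_stack", "video"}
        Container type; "auto" infers from the path.

    Returns
    -------
    frames : list of Frame
        In acquisition order, intensities normalized to [0, 1].
    meta : SequenceMeta
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"sequence path does not exist: {path}")
    if kind == "auto":
        kind = _infer_kind(path)

    raw_frames: list[np.ndarray] = []
    if kind == "image_dir":
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTENSIONS
        )
        if not files:
            raise IOError(f"no image files found in directory {path}")
        for f in files:
            if f.suffix.lower() in _LOSSY_EXTENSIONS:
                logger.warning(
                    "lossy-compressed input %s: compression artifacts degrade "
                    "keypoint matching",
                    f,
                )
            try:
                raw_frames.append(iio.imread(f))
            except Exception as exc:  # noqa: BLE001 - re-raise with filename
                raise IOError(f"unreadable image file: {f}") from exc
    elif kind == "tiff_stack":
        try:
            stack = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"unreadable TIFF stack: {path}") from exc
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        raw_frames = list(stack)
    elif kind == "video":
        logger.warning(
            "video container %s is typically lossy-compressed; compression "
            "artifacts degrade keypoint matching",
            path,
        )
        try:
            for im in iio.imiter(path):
                raw_frames.append(np.asarray(im))
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"unreadable video file: {path}") from exc
    else:
        raise ValueError(f"unknown sequence kind: {kind!r}")

    if not raw_frames:
        raise IOError(f"no frames decoded from {path}")

    frames: list[Frame] = []
    bit_depth = 8
    shape0 = _to_gray(raw_frames[0]).shape
    for i, raw in enumerate(raw_frames):
        gray = _to_gray(raw)
        if gray.shape != shape0:
            raise SequenceValidationError(
                f"frame {i} has size {gray.shape}, expected {shape0}: all "
                "frames in a sequence must share one size"
            )
        pixels, bit_depth = normalize_intensities(raw)
        frames.append(Frame(index=i, pixels=pixels))

    meta = SequenceMeta(
        n_frames=len(frames), source_path=str(path), bit_depth=bit_depth
    )
    return frames, meta


def write_frames(frames: Sequence[Frame], out_dir: str | os.PathLike) -> list[Path]:
    """Write frames as zero-padded 16-bit PNGs (lossless round-trip)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fr in frames:
        p = out_dir / f"frame_{fr.index:05d}.png"
        iio.imwrite(p, np.round(fr.pixels * 65535).astype(np.uint16))
        paths.append(p)
    return paths


def write_mosaic(
    mosaic,
    path: str | os.PathLike,
    emit_label_map: bool = False,
    bit_depth: int = 16,
) -> None:
    """Write a mosaic canvas (and optionally its provenance map) to disk.

    The canvas is written as a 8- or 16-bit TIFF/PNG by extension; uncovered
    pixels are written as 0.  With ``emit_label_map`` a companion
    ``<stem>_labels.tif`` holds the per-pixel source-frame index
    (:data:`UNCOVERED` for canvas pixels no frame reaches).
    """
    path = Path(path)
    pixels = np.asarray(mosaic.pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ValueError("mosaic canvas is empty")
    if bit_depth == 16:
        out = np.round(np.clip(pixels, 0, 1) * 65535).astype(np.uint16)
    elif bit_depth == 8:
        out = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, out)
        else:
            iio.imwrite(path, out)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write mosaic to {path}") from exc
    if emit_label_map:
        label_path = path.with_name(path.stem + "_labels.tif")
        tifffile.imwrite(label_path, np.asarray(mosaic.label_map, dtype=np.int32))


def write_run_report(report: dict, path: str | os.PathLike) -> None:
    """Serialize a pipeline run report (transforms, cuts, timings) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, default=_default))
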