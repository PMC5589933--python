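"""Shared fixtures: session-scoped synthetic textures and sweeps.

Everything is generated programmatically at fixed seeds; no fixture data
lives on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import confomosaic as cm


@pytest.fixture(scope="session")
def texture():
    """Default virtual tissue plane used across tests."""
    return cm.make_texture(1024, seed=11)


@pytest.fixture(scope="session")
def textured_frame(texture):
    """One 256x256 frame with realistic cell-like texture."""
    return cm.Frame(index=0, pixels=texture[:256, :256])


@pytest.fixture(scope="session")
def small_sweep(texture):
    """Clean 8-frame linear sweep (128-px frames, 30-px step)."""
    spec = cm.PathSpec(kind="linear", frame_size=128, step=30.0)
    return cm.simulate_sweep(texture, spec, n_frames=8, seed=5)


@pytest.fixture(scope="session")
def noiseless_integer_sweep(texture):
    """Integer-translation sweep with no noise: frames are exact crops."""
    spec = cm.PathSpec(
        kind="linear", frame_size=128, step=40.0,
        intensity_sigma=0.0, jitter_px=0.0,
    )
    return cm.simulate_sweep(texture, spec, n_frames=6, seed=3)


def assert_provenance_pure(mosaic, frames, segment):
    """Every covered mosaic pixel's value occurs verbatim in its source frame.

    The no-blending guarantee, checked exhaustively in nearest-neighbor mode:
    the pixel value must be bit-identical to the labeled frame's value at the
    inverse-mapped (rounded) position.
    """
    frame_by_index = {f.index: f for f in frames}
    x0, y0 = mosaic.offset
    covered = mosaic.coverage
    rows, cols = np.nonzero(covered)
    labels = mosaic.label_map[rows, cols]
    values = mosaic.pixels[rows, cols]
    for frame_index in np.unique(labels):
        frame = frame_by_index[int(frame_index)]
        i = segment.frame_indices.index(int(frame_index))
        inv = segment.cumulative_transforms[i].inverse()
        sel = labels == frame_index
        pts = np.column_stack([cols[sel] + x0, rows[sel] + y0])
        src = inv.apply(pts)
        sx = np.round(src[:, 0]).astype(int)
        sy = np.round(src[:, 1]).astype(int)
        assert np.all((sx >= 0) & (sx < frame.width)), "label points outside source"
        assert np.all((sy >= 0) & (sy < frame.height))
        np.testing.assert_array_equal(values[sel], frame.pixels[sy, sx])
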