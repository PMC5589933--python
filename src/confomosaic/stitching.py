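"""Graph-cut seam stitching: composite registered frames without blending.

Averaging or pyramid blending would blur the fine cellular texture that
makes confocal mosaics diagnostically useful, so every mosaic pixel keeps
the unaltered intensity of exactly one source frame.  Where two sources
overlap, the algorithm chooses a single continuous stitching boundary by
minimizing a local pixel-variation cost: for 4-adjacent overlap pixels p, q
assigned to different sources, the seam pays

    w(p, q) = |A(p) - B(p)| + |A(q) - B(q)|

where A is the existing composite and B the incoming warped frame (the
photomontage seam energy).  Pixels covered by only one source are hard-
constrained to it.  The binary labeling problem is solved exactly per
stitch by max-flow/min-cut; multi-frame overlap is handled by stitching
each frame against the growing composite in acquisition order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .io_frames import UNCOVERED, Frame
from .registration import AffineTransform
from .scene_cut import SubvideoSegment

logger = logging.getLogger(__name__)

EXISTING, INCOMING = 0, 1

# scipy's max-flow works on int32 capacities; float costs are quantized
# with an adaptive scale and clamped so no capacity (and no min-cut value)
# can overflow.  _BIG is the finite stand-in for the hard-constraint cost.
_CAP_LIMIT = 2**29
_BIG = 2**30


class SeamInfeasibleError(ValueError):
    """The seam problem's hard constraints cannot all be satisfied."""


@dataclass
class Canvas:
    """Mosaic canvas with per-pixel provenance.

    ``offset`` is the (x0, y0) of the canvas origin in segment-reference
    coordinates; ``label_map`` records, per covered pixel, the index of the
    frame whose unmodified intensity the pixel carries
    (:data:`~confomosaic.io_frames.UNCOVERED` elsewhere).
    """

    offset: tuple[float, float]
    pixels: np.ndarray
    label_map: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.shape != self.label_map.shape:
            raise ValueError("pixels and label_map must share one shape")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        return self.label_map != UNCOVERED


@dataclass
class SeamProblem:
    """Binary seam labeling over one overlap window.

    ``pairwise_unit[p]`` holds |A(p) - B(p)|; the cost of an edge (p, q)
    crossing the seam is ``pairwise_unit[p] + pairwise_unit[q]``.
    ``unary_costs[..., label]`` is zero for free pixels and prohibitively
    large where the hard membership constraints forbid ``label`` (pixels
    bordering single-source territory).
    """

    overlap_mask: np.ndarray  # bool (h, w): the variable pixels
    pairwise_unit: np.ndarray  # float (h, w)
    unary_costs: np.ndarray  # float (h, w, 2)
    window_origin: tuple[int, int] = (0, 0)  # (row, col) in the canvas

    def __post_init__(self) -> None:
        if self.overlap_mask.shape != self.pairwise_unit.shape:
            raise ValueError("overlap_mask and pairwise_unit shapes differ")
        if self.unary_costs.shape != (*self.overlap_mask.shape, 2):
            raise ValueError("unary_costs must have shape (h, w, 2)")
        if np.any(self.pairwise_unit < 0) or np.any(self.unary_costs < 0):
            raise ValueError("costs must be non-negative")


def warp_frame(
    frame: Frame,
    transform: AffineTransform,
    canvas_offset: tuple[float, float],
    canvas_shape: tuple[int, int],
    mode: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a frame onto a canvas grid by inverse mapping.

    ``transform`` maps frame coordinates into reference coordinates; each
    canvas pixel is pulled from ``transform^{-1}`` applied to its reference
    position.  Returns the warped intensities and a coverage mask, true
    exactly where the inverse-mapped location falls inside the source
    frame.  ``mode="nearest"`` preserves original pixel values bit-exactly;
    ``mode="bilinear"`` interpolates.
    """
    if mode not in ("nearest", "bilinear"):
        raise ValueError(f"unknown warp mode {mode!r}")
    h, w = canvas_shape
    x0, y0 = canvas_offset
    cols, rows = np.meshgrid(np.arange(w, dtype=np.float64),
                             np.arange(h, dtype=np.float64))
    inv = transform.inverse()
    A, t = inv.M[:2, :2], inv.M[:2, 2]
    sx = A[0, 0] * (cols + x0) + A[0, 1] * (rows + y0) + t[0]
    sy = A[1, 0] * (cols + x0) + A[1, 1] * (rows + y0) + t[1]

    fh, fw = frame.pixels.shape
    if mode == "nearest":
        rx = np.round(sx).astype(np.intp)
        ry = np.round(sy).astype(np.intp)
        mask = (rx >= 0) & (rx <= fw - 1) & (ry >= 0) & (ry <= fh - 1)
        warped = np.zeros(canvas_shape, dtype=frame.pixels.dtype)
        warped[mask] = frame.pixels[ry[mask], rx[mask]]
    else:
        mask = (sx >= 0) & (sx <= fw - 1) & (sy >= 0) & (sy <= fh - 1)
        warped = ndimage.map_coordinates(
            frame.pixels, [sy, sx], order=1, mode="constant", cval=0.0
        )
        warped[~mask] = 0.0
    return warped, mask


def build_seam_problem(
    existing_pixels: np.ndarray,
    existing_mask: np.ndarray,
    incoming_pixels: np.ndarray,
    incoming_mask: np.ndarray,
    window_origin: tuple[int, int] = (0, 0),
) -> SeamProblem:
    """Assemble the seam energy for one existing-vs-incoming overlap.

    All four arrays share one (windowed) canvas-aligned shape.  Overlap
    pixels bordering existing-only territory are hard-constrained to the
    existing label (and symmetrically for incoming-only territory): the
    seam must run strictly inside the overlap.  A pixel squeezed between
    both territories has its constraints dropped (logged) so thin overlaps
    remain solvable.
    """
    overlap = existing_mask & incoming_mask
    if not overlap.any():
        raise ValueError("overlap is empty: paste the incoming frame directly")
    only_a = existing_mask & ~incoming_mask
    only_b = incoming_mask & ~existing_mask

    diff = np.zeros(overlap.shape, dtype=np.float64)
    diff[overlap] = np.abs(
        existing_pixels[overlap].astype(np.float64)
        - incoming_pixels[overlap].astype(np.float64)
    )

    structure = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
    near_a = ndimage.binary_dilation(only_a, structure) & overlap
    near_b = ndimage.binary_dilation(only_b, structure) & overlap
    conflict = near_a & near_b
    if conflict.any():
        logger.debug(
            "%d overlap pixel(s) border both territories; constraints relaxed",
            int(conflict.sum()),
        )
        near_a &= ~conflict
        near_b &= ~conflict

    big = 1e6 * max(float(2.0 * diff.max()), 1.0)
    unary = np.zeros((*overlap.shape, 2), dtype=np.float64)
    unary[near_a, INCOMING] = big  # must keep the existing label
    unary[near_b, EXISTING] = big  # must take the incoming label
    return SeamProblem(
        overlap_mask=overlap,
        pairwise_unit=diff,
        unary_costs=unary,
        window_origin=window_origin,
    )


def _seam_graph_edges(problem: SeamProblem):
    """Node ids, 4-connected edge lists and float capacities for the cut."""
    mask = problem.overlap_mask
    ids = np.full(mask.shape, -1, dtype=np.intp)
    ids[mask] = np.arange(int(mask.sum()))

    pu = problem.pairwise_unit
    edges_u, edges_v, edges_w = [], [], []
    # horizontal then vertical neighbors, both inside the overlap
    for du, dv in ((0, 1), (1, 0)):
        a = mask[: mask.shape[0] - du, : mask.shape[1] - dv]
        b = mask[du:, dv:]
        both = a & b
        if not both.any():
            continue
        ia = ids[: mask.shape[0] - du, : mask.shape[1] - dv][both]
        ib = ids[du:, dv:][both]
        w = (pu[: pu.shape[0] - du, : pu.shape[1] - dv][both]
             + pu[du:, dv:][both])
        edges_u.append(ia)
        edges_v.append(ib)
        edges_w.append(w)
    if edges_u:
        return ids, (np.concatenate(edges_u), np.concatenate(edges_v),
                     np.concatenate(edges_w))
    return ids, (np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0))


def seam_energy(problem: SeamProblem, labels: np.ndarray) -> float:
    """Energy of a labeling: cut pairwise costs plus finite unary costs.

    Hard-constraint (prohibitive) unary costs count too, so an infeasible
    labeling scores astronomically; feasible ones pay only the seam.
    """
    mask = problem.overlap_mask
    ids, (eu, ev, ew) = _seam_graph_edges(problem)
    lab = labels[mask]
    energy = float(ew[lab[eu] != lab[ev]].sum()) if eu.size else 0.0
    unary = problem.unary_costs[mask]
    energy += float(unary[np.arange(lab.size), lab].sum())
    return energy


def solve_seam(problem: SeamProblem) -> tuple[np.ndarray, float]:
    """Exact minimum-energy binary labeling of the overlap via min-cut.

    Returns ``(labels, energy)`` where ``labels`` is an (h, w) int8 array
    with 0 = existing, 1 = incoming on overlap pixels (0 elsewhere), and
    ``energy`` is the float seam energy of the returned assignment.
    """
    mask = problem.overlap_mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("seam problem has an empty overlap")
    ids, (eu, ev, ew) = _seam_graph_edges(problem)

    unary = problem.unary_costs[mask]  # (n, 2)
    if np.any((unary[:, 0] > 0) & (unary[:, 1] > 0)):
        raise SeamInfeasibleError("a pixel is forbidden both labels")

    # adaptive integer quantization: scale by an upper bound on the optimal
    # energy (best heuristic labeling) so the min cut keeps full precision;
    # costlier capacities are clamped — they can never sit in the optimum
    bound = min(
        seam_energy(problem, np.zeros(mask.shape, np.int8)),
        seam_energy(problem, np.ones(mask.shape, np.int8)),
        _constraint_respecting_energy(problem),
    )
    scale = _CAP_LIMIT / max(bound, 1e-12)
    max_finite = max(float(ew.max()) if ew.size else 0.0,
                     float(unary[unary < 1e5].max()) if np.any(unary < 1e5) else 0.0)
    if max_finite > 0:
        scale = min(scale, _CAP_LIMIT / max_finite)

    def q(x):
        return np.minimum(np.round(x * scale), _CAP_LIMIT).astype(np.int64)

    src, snk = n, n + 1
    rows = [eu, ev]
    cols = [ev, eu]
    caps = [q(ew), q(ew)]
    nodes = np.arange(n)
    s_cap = np.where(unary[:, INCOMING] > 1e5, _BIG, q(unary[:, INCOMING]))
    t_cap = np.where(unary[:, EXISTING] > 1e5, _BIG, q(unary[:, EXISTING]))
    rows += [np.full(n, src), nodes, nodes, np.full(n, snk)]
    cols += [nodes, np.full(n, src), np.full(n, snk), nodes]
    caps += [s_cap, np.zeros(n, np.int64), t_cap, np.zeros(n, np.int64)]

    graph = csr_matrix(
        (np.concatenate(caps),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 2, n + 2),
    )
    graph.data = graph.data.astype(np.int32)  # scipy max-flow is int32
    result = maximum_flow(graph, src, snk)

    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, src, directed=True,
                                   return_predecessors=False)

    lab = np.ones(n, dtype=np.int8)  # unreachable side of the cut = incoming
    lab[reachable[reachable < n]] = EXISTING
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[mask] = lab
    return labels, seam_energy(problem, labels)


def _constraint_respecting_energy(problem: SeamProblem) -> float:
    """Energy of the heuristic 'flood from the incoming boundary' labeling."""
    forced_b = problem.unary_costs[..., EXISTING] > 0
    labels = np.zeros(problem.overlap_mask.shape, np.int8)
    labels[forced_b] = INCOMING
    return seam_energy(problem, labels)


def _projected_bbox(transform: AffineTransform, frame_shape: tuple[int, int]
                    ) -> np.ndarray:
    h, w = frame_shape
    corners = np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [0.0, h - 1.0], [w - 1.0, h - 1.0]]
    )
    return transform.apply(corners)


def canvas_geometry(
    segment: SubvideoSegment, frame_shape: tuple[int, int]
) -> tuple[tuple[float, float], tuple[int, int]]:
    """Offset and shape of the union of warped frame footprints."""
    pts = np.vstack([
        _projected_bbox(tf, frame_shape) for tf in segment.cumulative_transforms
    ])
    x0, y0 = np.floor(pts.min(axis=0))
    x1, y1 = np.ceil(pts.max(axis=0))
    return (float(x0), float(y0)), (int(y1 - y0) + 1, int(x1 - x0) + 1)


def composite_segment(
    segment: SubvideoSegment,
    frames: list[Frame],
    warp_mode: str = "bilinear",
) -> Canvas:
    """Warp and stitch a segment's frames into one mosaic canvas.

    Frames are stitched sequentially against the growing composite in
    acquisition order; the label map records each covered pixel's source
    frame, whose unmodified (nearest mode) or interpolated (bilinear mode)
    value it carries.
    """
    frame_by_index = {f.index: f for f in frames}
    shape0 = frame_by_index[segment.start_index].pixels.shape
    offset, shape = canvas_geometry(segment, shape0)
    pixels = np.zeros(shape, dtype=np.float64)
    label_map = np.full(shape, UNCOVERED, dtype=np.int32)

    for i, frame_index in enumerate(segment.frame_indices):
        frame = frame_by_index[frame_index]
        tf = segment.cumulative_transforms[i]

        # tight window around this frame's footprint keeps the warp cheap
        bbox = _projected_bbox(tf, frame.pixels.shape)
        c0 = max(int(np.floor(bbox[:, 0].min() - offset[0])) - 1, 0)
        r0 = max(int(np.floor(bbox[:, 1].min() - offset[1])) - 1, 0)
        c1 = min(int(np.ceil(bbox[:, 0].max() - offset[0])) + 2, shape[1])
        r1 = min(int(np.ceil(bbox[:, 1].max() - offset[1])) + 2, shape[0])
        win_offset = (offset[0] + c0, offset[1] + r0)
        win_shape = (r1 - r0, c1 - c0)

        warped, mask = warp_frame(frame, tf, win_offset, win_shape, warp_mode)
        win_pixels = pixels[r0:r1, c0:c1]
        win_labels = label_map[r0:r1, c0:c1]
        existing_mask = win_labels != UNCOVERED
        overlap = existing_mask & mask

        if not overlap.any():
            if existing_mask.any() or i > 0:
                logger.info(
                    "frame %d does not overlap the composite; pasted directly",
                    frame_index,
                )
            take = mask
        else:
            problem = build_seam_problem(
                win_pixels, existing_mask, warped, mask,
                window_origin=(r0, c0),
            )
            labels, energy = solve_seam(problem)
            logger.debug("frame %d seam energy %.6g", frame_index, energy)
            take = (mask & ~existing_mask) | (overlap & (labels == INCOMING))

        win_pixels[take] = warped[take]
        win_labels[take] = frame_index

    return Canvas(offset=offset, pixels=pixels, label_map=label_map)
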