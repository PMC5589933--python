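"""Warping, seam energies, min-cut optimality, and provenance-pure mosaics."""


import numpy as np
import pytest
from scipy import ndimage

import confomosaic as cm
from confomosaic.stitching import EXISTING, INCOMING

from conftest import assert_provenance_pure


def _affine(a11=1.0, a12=0.0, tx=0.0, a21=0.0, a22=1.0, ty=0.0):
    return cm.AffineTransform.from_params(a11, a12, tx, a21, a22, ty)


def make_problem(pairwise_unit, forced_existing=None, forced_incoming=None):
    """SeamProblem over a full-rectangle overlap with optional forced pixels."""
    pu = np.asarray(pairwise_unit, dtype=float)
    mask = np.ones(pu.shape, dtype=bool)
    big = 1e6 * max(2.0 * pu.max(), 1.0)
    unary = np.zeros((*pu.shape, 2))
    if forced_existing is not None:
        unary[forced_existing, INCOMING] = big
    if forced_incoming is not None:
        unary[forced_incoming, EXISTING] = big
    return cm.SeamProblem(overlap_mask=mask, pairwise_unit=pu,
                          unary_costs=unary)


def brute_force_minimum(problem):
    """Exhaustive enumeration over all 2^n labelings of the overlap pixels.

    Edges and energies are derived here from scratch (independent of the
    solver's graph construction).
    """
    mask = problem.overlap_mask
    coords = [tuple(c) for c in np.argwhere(mask)]
    n = len(coords)
    assert n <= 20, "enumeration oracle limited to small instances"
    index = {c: i for i, c in enumerate(coords)}
    eu, ev, ew = [], [], []
    for (r, c), i in index.items():
        for rr, cc in ((r, c + 1), (r + 1, c)):
            j = index.get((rr, cc))
            if j is not None:
                eu.append(i)
                ev.append(j)
                ew.append(problem.pairwise_unit[r, c]
                          + problem.pairwise_unit[rr, cc])
    eu, ev, ew = np.array(eu), np.array(ev), np.array(ew, dtype=float)
    bits = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(np.int8)
    energies = (bits[:, eu] != bits[:, ev]).astype(float) @ ew
    un = problem.unary_costs[mask]
    energies += bits @ un[:, 1] + (1 - bits) @ un[:, 0]
    return float(energies.min())


def independent_energy(problem, labels):
    """Plain-loop cost summation, independent of the solver's vector path."""
    mask, pu = problem.overlap_mask, problem.pairwise_unit
    h, w = mask.shape
    total = 0.0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            total += problem.unary_costs[r, c, labels[r, c]]
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < h and cc < w and mask[rr, cc]:
                    if labels[r, c] != labels[rr, cc]:
                        total += pu[r, c] + pu[rr, cc]
    return total


class TestWarpFrame:
    def test_identity_transform_reproduces_frame(self, textured_frame):
        warped, mask = cm.warp_frame(
            textured_frame, _affine(), (0.0, 0.0), (256, 256), "nearest"
        )
        np.testing.assert_array_equal(warped, textured_frame.pixels)
        assert mask.all()

    @pytest.mark.parametrize("mode", ["nearest", "bilinear"])
    def test_integer_translation_bit_identical(self, textured_frame, mode):
        warped, mask = cm.warp_frame(
            textured_frame, _affine(tx=5.0), (0.0, 0.0), (256, 266), mode
        )
        assert mask[:, 5:261].all() and not mask[:, :5].any()
        np.testing.assert_array_equal(
            warped[:, 5:261], textured_frame.pixels
        )

    def test_rotated_disk_coverage_area_preserved(self):
        """A 45-degree rotation preserves footprint area within 1%."""
        size = 200
        frame = cm.Frame(index=0, pixels=np.ones((size, size)))
        c = (size - 1) / 2.0
        s2 = np.sqrt(2) / 2
        # rotate about the frame center: p' = R(p - c) + c + offset
        tx = c - s2 * c + s2 * c  # R @ (-c,-c) folded into translation
        rot = cm.AffineTransform(np.array([
            [s2, -s2, c - s2 * c + s2 * c + 60],
            [s2, s2, c - s2 * c - s2 * c + 160],
            [0, 0, 1.0],
        ]))
        _, mask = cm.warp_frame(frame, rot, (0.0, 0.0), (420, 420), "bilinear")
        assert mask.sum() == pytest.approx((size - 1) ** 2, rel=0.01)


class TestBuildSeamProblem:
    def test_identical_sources_zero_costs(self):
        a = np.random.default_rng(0).random((8, 8))
        mask = np.ones((8, 8), bool)
        problem = cm.build_seam_problem(a, mask, a.copy(), mask)
        assert problem.pairwise_unit.max() == 0.0
        labels, energy = cm.solve_seam(problem)
        assert energy == 0.0

    def test_hard_constraints_follow_territories(self):
        a = np.zeros((4, 8))
        b = np.ones((4, 8))
        mask_a = np.zeros((4, 8), bool); mask_a[:, :6] = True
        mask_b = np.zeros((4, 8), bool); mask_b[:, 2:] = True
        problem = cm.build_seam_problem(a, mask_a, b, mask_b)
        assert problem.overlap_mask.sum() == 4 * 4
        # column 2 borders existing-only territory, column 5 incoming-only
        assert (problem.unary_costs[:, 2, INCOMING] > 0).all()
        assert (problem.unary_costs[:, 5, EXISTING] > 0).all()
        labels, _ = cm.solve_seam(problem)
        assert (labels[:, 2] == EXISTING).all()
        assert (labels[:, 5] == INCOMING).all()

    def test_empty_overlap_rejected(self):
        m1 = np.zeros((4, 4), bool); m1[:, :2] = True
        with pytest.raises(ValueError, match="overlap"):
            cm.build_seam_problem(np.zeros((4, 4)), m1, np.ones((4, 4)), ~m1)


class TestSolveSeam:
    def test_zero_costs_zero_energy(self):
        problem = make_problem(np.zeros((5, 5)))
        _, energy = cm.solve_seam(problem)
        assert energy == 0.0

    def test_seam_avoids_differing_stripe(self):
        """Sources differ only in one vertical stripe; the optimal seam
        routes around it at zero cost."""
        rng = np.random.default_rng(1)
        base = rng.random((16, 16))
        other = base.copy()
        other[:, 7:9] += 0.5  # amplitude-delta stripe
        mask = np.ones((16, 16), bool)
        forced_a = np.zeros((16, 16), bool); forced_a[:, 0] = True
        forced_b = np.zeros((16, 16), bool); forced_b[:, -1] = True
        pu = np.abs(base - other)
        problem = make_problem(pu, forced_a, forced_b)
        labels, energy = cm.solve_seam(problem)
        assert energy == 0.0
        assert (labels[:, 0] == EXISTING).all()
        assert (labels[:, -1] == INCOMING).all()

    def test_single_pixel_overlap_degenerate(self):
        problem = make_problem(np.array([[0.3]]))
        labels, energy = cm.solve_seam(problem)
        assert energy == 0.0 and labels.shape == (1, 1)

    def test_infeasible_constraints_rejected(self):
        forced = np.ones((2, 2), bool)
        with pytest.raises(cm.SeamInfeasibleError):
            cm.solve_seam(make_problem(np.ones((2, 2)), forced, forced))

    @pytest.mark.parametrize("seed", range(12))
    def test_energy_equals_brute_force_on_4x4(self, seed):
        rng = np.random.default_rng(seed)
        pu = rng.random((4, 4))
        forced_a = np.zeros((4, 4), bool); forced_a[:, 0] = rng.random(4) < 0.7
        forced_b = np.zeros((4, 4), bool); forced_b[:, -1] = rng.random(4) < 0.7
        problem = make_problem(pu, forced_a, forced_b)
        labels, energy = cm.solve_seam(problem)
        assert energy == pytest.approx(brute_force_minimum(problem), abs=1e-9)
        # self-consistency against an independent summation routine
        assert energy == pytest.approx(
            independent_energy(problem, labels), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_never_worse_than_straight_seams_64x64(self, seed):
        rng = np.random.default_rng(100 + seed)
        pu = rng.random((64, 64))
        forced_a = np.zeros((64, 64), bool); forced_a[:, 0] = True
        forced_b = np.zeros((64, 64), bool); forced_b[:, -1] = True
        problem = make_problem(pu, forced_a, forced_b)
        _, energy = cm.solve_seam(problem)
        for col in range(1, 64):
            straight = np.zeros((64, 64), np.int8)
            straight[:, col:] = INCOMING
            assert energy <= cm.seam_energy(problem, straight) + 1e-9

    def test_label_continuity_two_connected_regions(self):
        """The cut splits the overlap into two 4-connected regions, each
        touching its hard-constrained side."""
        rng = np.random.default_rng(7)
        pu = rng.random((32, 32)) + 0.05
        forced_a = np.zeros((32, 32), bool); forced_a[:, 0] = True
        forced_b = np.zeros((32, 32), bool); forced_b[:, -1] = True
        problem = make_problem(pu, forced_a, forced_b)
        labels, _ = cm.solve_seam(problem)
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for side, col in ((EXISTING, 0), (INCOMING, 31)):
            region = labels == side
            _, n_components = ndimage.label(region, structure)
            assert n_components == 1
            assert region[:, col].all()


class TestCompositeSegment:
    def test_single_frame_segment_is_the_frame(self, textured_frame):
        seg = cm.SubvideoSegment(0, 0, [cm.AffineTransform.identity()])
        mosaic = cm.composite_segment(seg, [textured_frame], "nearest")
        np.testing.assert_array_equal(mosaic.pixels, textured_frame.pixels)
        assert (mosaic.label_map == 0).all()

    def test_two_identical_frames_idempotent(self, textured_frame):
        frames = [textured_frame,
                  cm.Frame(index=1, pixels=textured_frame.pixels.copy())]
        seg = cm.SubvideoSegment(
            0, 1, [cm.AffineTransform.identity()] * 2
        )
        mosaic = cm.composite_segment(seg, frames, "nearest")
        np.testing.assert_array_equal(mosaic.pixels, textured_frame.pixels)
        assert set(np.unique(mosaic.label_map)) <= {0, 1}

    def test_translation_sweep_reproduces_texture_exactly(
        self, noiseless_integer_sweep, texture
    ):
        """Noiseless integer-translation sweep, nearest warping: the mosaic
        equals the ground-truth texture crop bit-exactly."""
        frames, truth = noiseless_integer_sweep
        ref_inv = truth.true_transforms[0].inverse()
        cumulative = [ref_inv.compose(tf) for tf in truth.true_transforms]
        seg = cm.SubvideoSegment(0, len(frames) - 1, cumulative)
        mosaic = cm.composite_segment(seg, frames, "nearest")
        # canvas offset in texture coordinates
        x0, y0 = mosaic.offset
        t0 = truth.true_transforms[0]
        tx0, ty0 = int(t0.M[0, 2] + x0), int(t0.M[1, 2] + y0)
        covered = mosaic.coverage
        crop = texture[ty0:ty0 + mosaic.height, tx0:tx0 + mosaic.width]
        np.testing.assert_array_equal(mosaic.pixels[covered], crop[covered])
        assert covered.all()  # rectilinear sweep covers the whole canvas
        assert_provenance_pure(mosaic, frames, seg)

    def test_mosaic_extent_is_union_of_footprints(self, small_sweep):
        frames, truth = small_sweep
        ref_inv = truth.true_transforms[0].inverse()
        cumulative = [ref_inv.compose(tf) for tf in truth.true_transforms]
        seg = cm.SubvideoSegment(0, len(frames) - 1, cumulative)
        mosaic = cm.composite_segment(seg, frames, "nearest")
        corners = np.vstack([
            tf.apply(np.array([[0, 0], [127, 0], [0, 127], [127, 127]], float))
            for tf in cumulative
        ])
        x0, y0 = mosaic.offset
        assert abs(x0 - np.floor(corners[:, 0].min())) <= 1
        assert abs(y0 - np.floor(corners[:, 1].min())) <= 1
        assert abs((x0 + mosaic.width - 1) - np.ceil(corners[:, 0].max())) <= 1
        assert abs((y0 + mosaic.height - 1) - np.ceil(corners[:, 1].max())) <= 1
        assert_provenance_pure(mosaic, frames, seg)
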