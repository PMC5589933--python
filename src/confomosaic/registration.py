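"""Robust inter-frame affine estimation: RANSAC, pruning, penalized refit.

The motion between consecutive frames of a handheld acquisition is modeled
as a 6-parameter affine transform (rotation/scale/shear plus translation),
represented as a 3x3 homogeneous matrix ``M`` mapping current-frame
coordinates into previous-frame coordinates.  Estimation proceeds in three
stages:

1. RANSAC over random 3-match subsets (an affine is exactly determined by
   3 non-collinear correspondences), scoring each candidate by its
   truncated mean l1 reprojection error over all matches;
2. pruning of matches whose l1 reprojection error under the selected model
   exceeds a pixel tolerance (default 50 px, |dx| + |dy|);
3. a final fit over the surviving inliers minimizing the sum of l2
   residual norms plus a quadratic penalty on scale change and shear,
   which guards against over-fitting when inliers concentrate in one
   region of the frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError

logger = logging.getLogger(__name__)

DEFAULT_N_TRIALS = 3000
DEFAULT_INLIER_TOL = 50.0  # l1 pixels, |dx| + |dy|

#: Penalty weight reference: lambda = n_inliers * frame_side / _LAMBDA_SCALE
#: gives 1e3 for ~500 homogeneously spread inliers on a 1000-px frame, where
#: the penalty contributes ~1% of the data-term gradient.
_LAMBDA_SCALE = 500.0
DEFAULT_LAMBDA_REG = 1.0e3  # absolute weight at clinical geometry

#: Determinant magnitude below which a 3-point sample is treated as collinear.
_DEGENERACY_EPS = 1e-9


class DegenerateSampleError(ValueError):
    """The 3 previous-frame points are (numerically) collinear."""


class RegistrationInfeasible(RuntimeError):
    """Too few or too degenerate matches to estimate a transform.

    Downstream this signal forces a scene cut: the pair behaves like
    non-overlapping or unusable frames.
    """


@dataclass(frozen=True)
class AffineTransform:
    """3x3 homogeneous affine, bottom row (0, 0, 1).

    The upper-left 2x2 block carries rotation/scale/shear; the third
    column carries translation in pixels.  ``apply`` maps (x, y) points
    from the current frame into the previous (or reference) frame.
    """

    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=np.float64)
        if M.shape != (3, 3):
            raise ValueError(f"affine matrix must be 3x3, got {M.shape}")
        if not np.array_equal(M[2], (0.0, 0.0, 1.0)):
            raise ValueError("bottom row must be exactly (0, 0, 1)")
        if abs(np.linalg.det(M[:2, :2])) <= 0.0:
            raise ValueError("2x2 linear block must be invertible")
        M = M.copy()
        M.setflags(write=False)
        object.__setattr__(self, "M", M)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3))

    @classmethod
    def from_params(cls, a11, a12, tx, a21, a22, ty) -> "AffineTransform":
        return cls(np.array([[a11, a12, tx], [a21, a22, ty], [0.0, 0.0, 1.0]]))

    @property
    def params(self) -> np.ndarray:
        """(a11, a12, tx, a21, a22, ty)."""
        return self.M[:2].ravel()

    @property
    def trace(self) -> float:
        """Trace of the homogeneous matrix: a11 + a22 + 1 (3 for pure translation)."""
        return float(np.trace(self.M))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) (x, y) points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.M[:2, :2].T + self.M[:2, 2]

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self . other (apply ``other`` first)."""
        return AffineTransform(self.M @ other.M)

    def inverse(self) -> "AffineTransform":
        Minv = np.linalg.inv(self.M)
        Minv[2] = (0.0, 0.0, 1.0)
        return AffineTransform(Minv)


@dataclass
class RegistrationResult:
    """Outcome of RANSAC + pruning for one frame pair."""

    transform: AffineTransform
    inlier_indices: np.ndarray  # indices into the input match list
    n_ransac_trials: int
    mean_residual: float  # mean l1 reprojection error over inliers (px)
    spatial_spread: float  # inlier convex-hull area / frame area (diagnostic)


def fit_affine_exact(curr: np.ndarray, prev: np.ndarray) -> AffineTransform:
    """Affine exactly mapping 3 current-frame points onto 3 previous-frame points.

    Raises :class:`DegenerateSampleError` when the points are collinear.
    """
    curr = np.asarray(curr, dtype=np.float64).reshape(3, 2)
    prev = np.asarray(prev, dtype=np.float64).reshape(3, 2)
    A = np.column_stack([curr, np.ones(3)])
    det = np.linalg.det(A)
    scale = max(1.0, np.abs(curr).max()) ** 2
    if abs(det) <= _DEGENERACY_EPS * scale:
        raise DegenerateSampleError("sample points are collinear")
    coef = np.linalg.solve(A, prev)  # (3, 2): rows (a.1, a.2, t)
    return AffineTransform.from_params(
        coef[0, 0], coef[1, 0], coef[2, 0], coef[0, 1], coef[1, 1], coef[2, 1]
    )


def _l1_residuals(params6: np.ndarray, curr_h: np.ndarray, prev: np.ndarray
                  ) -> np.ndarray:
    """l1 reprojection errors; params6 = (a11, a12, tx, a21, a22, ty)."""
    pred = curr_h @ params6.reshape(2, 3).T
    return np.abs(pred - prev).sum(axis=1)


def ransac_affine(
    curr: np.ndarray,
    prev: np.ndarray,
    n_trials: int = DEFAULT_N_TRIALS,
    inlier_tol: float = DEFAULT_INLIER_TOL,
    seed: int | np.random.Generator | None = 0,
    frame_shape: tuple[int, int] | None = None,
) -> RegistrationResult:
    """Select the affine that generalizes best over random 3-match subsets.

    Parameters
    ----------
    curr, prev : (n, 2) arrays
        Matched point coordinates in the current and previous frame.
    n_trials : int
        Number of random 3-subsets to try.
    inlier_tol : float
        l1 pixel tolerance; matches reprojecting worse than this under the
        selected model are pruned.
    seed : int or Generator
        Sampling seed; fixed seed gives bit-reproducible output.
    frame_shape : (height, width), optional
        Enables the spatial-spread diagnostic.

    Notes
    -----
    Each candidate model is scored by the mean of per-match l1 reprojection
    errors truncated at ``inlier_tol`` (MSAC-style), so gross outliers
    saturate rather than dominate.
    """
    curr = np.asarray(curr, dtype=np.float64).reshape(-1, 2)
    prev = np.asarray(prev, dtype=np.float64).reshape(-1, 2)
    n = curr.shape[0]
    if n < 3:
        raise RegistrationInfeasible(f"only {n} matches; need at least 3")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    curr_h = np.column_stack([curr, np.ones(n)])

    # sample all trials up-front (without replacement within a trial)
    samples = np.empty((n_trials, 3), dtype=np.intp)
    for t in range(n_trials):
        samples[t] = rng.choice(n, size=3, replace=False)

    # batched exact fits: A_t theta_t = B_t with A_t the 3x3 homogeneous
    # sample matrix; degenerate (collinear) trials are skipped
    A = curr_h[samples]  # (T, 3, 3)
    B = prev[samples]  # (T, 3, 2)
    dets = np.linalg.det(A)
    scale = max(1.0, np.abs(curr).max()) ** 2
    valid = np.abs(dets) > _DEGENERACY_EPS * scale
    if not valid.any():
        raise RegistrationInfeasible("all RANSAC trials drew degenerate samples")
    coef = np.linalg.solve(A[valid], B[valid])  # (V, 3, 2)

    # score candidates in chunks: truncated mean l1 error over all matches
    best_score = np.inf
    best_coef = None
    chunk = max(1, int(2.5e7) // max(n, 1))
    for start in range(0, coef.shape[0], chunk):
        c = coef[start:start + chunk]  # (C, 3, 2)
        pred = np.einsum("nk,ckd->cnd", curr_h, c)
        err = np.abs(pred - prev[None]).sum(axis=2)  # (C, n) l1
        np.minimum(err, inlier_tol, out=err)
        scores = err.mean(axis=1)
        i = int(np.argmin(scores))
        if scores[i] < best_score:
            best_score = float(scores[i])
            best_coef = c[i]

    params6 = np.array([best_coef[0, 0], best_coef[1, 0], best_coef[2, 0],
                        best_coef[0, 1], best_coef[1, 1], best_coef[2, 1]])
    residuals = _l1_residuals(params6, curr_h, prev)
    inlier_indices = np.flatnonzero(residuals <= inlier_tol)
    if inlier_indices.size < 3:
        raise RegistrationInfeasible(
            f"only {inlier_indices.size} matches survive the "
            f"{inlier_tol:g}-pixel pruning"
        )

    transform = AffineTransform.from_params(*params6)
    spread = _spatial_spread(curr[inlier_indices], frame_shape)
    return RegistrationResult(
        transform=transform,
        inlier_indices=inlier_indices,
        n_ransac_trials=n_trials,
        mean_residual=float(residuals[inlier_indices].mean()),
        spatial_spread=spread,
    )


def _spatial_spread(points: np.ndarray, frame_shape) -> float:
    if frame_shape is None or points.shape[0] < 3:
        return float("nan")
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0
    return float(hull.volume / (frame_shape[0] * frame_shape[1]))


def auto_lambda_reg(n_inliers: int, frame_side: float) -> float:
    """Scale-aware default penalty weight for the final fit.

    The data term's sensitivity to the linear block grows with both the
    number of inliers and the pixel extent of the frame, so a fixed
    penalty weight that is gentle at clinical geometry (~500 inliers,
    1000-px frames, where it contributes ~1% of the data gradient) would
    dominate small test frames.  This keeps the relative strength
    constant: ``n_inliers * frame_side / 500`` (= 1e3 at clinical
    geometry).
    """
    return n_inliers * frame_side / _LAMBDA_SCALE


def refine_affine_penalized(
    curr: np.ndarray,
    prev: np.ndarray,
    init: AffineTransform,
    lambda_reg: float | None = None,
    squared: bool = False,
    max_iter: int = 200,
    gtol: float = 1e-8,
    frame_shape: tuple[int, int] | None = None,
) -> AffineTransform:
    """Final fit: sum of l2 residual norms + scale-change/shear penalty.

    Minimizes ``sum_i ||M p_i - q_i||_2 + lambda_reg * [(a11-1)^2 +
    (a22-1)^2 + a12^2 + a21^2]`` over the 6 affine parameters, starting
    from ``init``.  With ``lambda_reg=None`` the weight is sized by
    :func:`auto_lambda_reg` from the inlier count and frame side (taken
    from ``frame_shape``, or the coordinate extent when absent).  With
    ``squared=True`` the data term uses squared norms instead, which has
    a closed-form ridge solution (useful for testing and as a faster
    variant).

    On optimizer failure the initial transform is returned with a warning.
    """
    curr = np.asarray(curr, dtype=np.float64).reshape(-1, 2)
    prev = np.asarray(prev, dtype=np.float64).reshape(-1, 2)
    n = curr.shape[0]
    if n < 3:
        raise RegistrationInfeasible(f"only {n} inliers; need at least 3")
    if lambda_reg is None:
        if frame_shape is not None:
            side = float(max(frame_shape))
        else:
            side = float(max(np.ptp(curr, axis=0).max(), 1.0))
        lambda_reg = auto_lambda_reg(n, side)
    curr_h = np.column_stack([curr, np.ones(n)])

    if squared:
        return _ridge_affine(curr_h, prev, lambda_reg)

    # parameter vector (a11, a12, tx, a21, a22, ty); penalty pulls the
    # linear block toward the identity, never the translation
    target = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])
    pen_mask = np.array([1.0, 1.0, 0.0, 1.0, 1.0, 0.0])

    def objective(p):
        pred = curr_h @ p.reshape(2, 3).T
        r = pred - prev
        norms = np.sqrt((r * r).sum(axis=1))
        data = norms.sum()
        dp = p - target
        grad_pen = 2.0 * lambda_reg * pen_mask * dp
        safe = np.maximum(norms, 1e-12)
        unit = r / safe[:, None]
        grad_data = np.concatenate(
            [curr_h.T @ unit[:, 0], curr_h.T @ unit[:, 1]]
        )
        return data + lambda_reg * np.sum(pen_mask * dp * dp), grad_data + grad_pen

    # the sum-of-norms data term is non-smooth at zero residuals, where
    # quasi-Newton steps stall; warm-start at the closed-form ridge solution
    # (squared data term, same penalty) and keep whichever candidate scores
    # best under the true objective
    ridge = _ridge_affine(curr_h, prev, lambda_reg)
    res = minimize(
        objective, ridge.params.copy(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    candidates = [init.params, ridge.params]
    if np.all(np.isfinite(res.x)):
        candidates.append(res.x)
    else:
        logger.warning("penalized refinement diverged; falling back")
    best = min(candidates, key=lambda p: objective(p)[0])
    try:
        return AffineTransform.from_params(*best)
    except ValueError:
        logger.warning("penalized refinement produced a singular model; "
                       "keeping RANSAC model")
        return init


def _ridge_affine(curr_h: np.ndarray, prev: np.ndarray, lambda_reg: float
                  ) -> AffineTransform:
    """Closed-form squared-residual variant (separable per output coordinate)."""
    G = curr_h.T @ curr_h
    D = np.diag([lambda_reg, lambda_reg, 0.0])
    lhs = G + D
    sol_x = np.linalg.solve(lhs, curr_h.T @ prev[:, 0] + lambda_reg * np.array([1.0, 0.0, 0.0]))
    sol_y = np.linalg.solve(lhs, curr_h.T @ prev[:, 1] + lambda_reg * np.array([0.0, 1.0, 0.0]))
    return AffineTransform.from_params(
        sol_x[0], sol_x[1], sol_x[2], sol_y[0], sol_y[1], sol_y[2]
    )


def max_corner_displacement(
    a: AffineTransform, b: AffineTransform, frame_shape: tuple[int, int]
) -> float:
    """Largest displacement between the two transforms over the frame corners.

    The standard registration-accuracy summary: evaluate both transforms at
    the 4 corners of an (height, width) frame and take the maximum
    Euclidean gap.
    """
    h, w = frame_shape
    corners = np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [0.0, h - 1.0], [w - 1.0, h - 1.0]]
    )
    da = a.apply(corners) - b.apply(corners)
    return float(np.sqrt((da * da).sum(axis=1)).max())
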