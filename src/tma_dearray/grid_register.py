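"""Grid-deformation estimation and array-coordinate assignment.

The de-arraying model assumes the observed core centers are the image of an
ideal square design grid under a deformation that splits into an affine part
and a smooth non-linear residual.  The affine part ("oblique grid") is
estimated by robust statistics over nearest-neighbour pairs: a 30%-trimmed
mean of pair lengths gives the spacing d_bar, trimmed means of pair angles
split at pi/4 give the two principal directions (alpha_bar, beta_bar), and a
global translation t_hat is fit by alternating nearest-lattice-node
assignment and averaging.  The non-linear part is a thin-plate spline (TPS,
kernel U(r^2) = r^2 log r^2) interpolating associated (ideal node, observed
center) pairs; association and TPS fitting alternate until the warped grid
stops moving.  Array coordinates are read off as the nearest warped node,
and empty nodes are offered to a second segmentation pass (refinement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ellipse_fit import Ellipse, FitConfig, FitResult, fit_single
from .io_preprocess import IntensityImage, extract_patch

__all__ = [
    "ObliqueGrid",
    "TpsModel",
    "CoreRecord",
    "DearrayResult",
    "neighbor_pairs",
    "robust_spacing",
    "robust_angles",
    "estimate_translation",
    "estimate_oblique_grid",
    "tps_fit",
    "associate",
    "register",
    "assign_coordinates",
    "refine",
]

TRIM_FRACTION = 0.30  # fraction of most-extreme values discarded in total
DELTA_FACTOR = 0.4  # association radius as a fraction of d_bar
CONVERGENCE_TOL = 1e-2  # px, max warped-node displacement between iterations


# ---------------------------------------------------------------------------
# affine (oblique grid) initialization
# ---------------------------------------------------------------------------


@dataclass
class ObliqueGrid:
    """Affine summary of the deformed grid: x = t + d_bar * M_{alpha,beta} p."""

    d: float
    alpha: float
    beta: float
    t: np.ndarray

    @property
    def basis(self) -> np.ndarray:
        """2x2 change-of-basis matrix with unit columns (cos a, sin a), (cos b, sin b)."""
        return np.array(
            [
                [np.cos(self.alpha), np.cos(self.beta)],
                [np.sin(self.alpha), np.sin(self.beta)],
            ]
        )

    def lattice_map(self, p: np.ndarray) -> np.ndarray:
        """F(p) = d_bar * M p   (no translation)."""
        return (self.d * self.basis @ np.atleast_2d(p).T).T

    def affine_map(self, p: np.ndarray) -> np.ndarray:
        """A(p) = t_hat + F(p)."""
        return self.t + self.lattice_map(p)

    def array_coords(self, x: np.ndarray) -> np.ndarray:
        """Real-valued array coordinates M^-1 (x - t) / d_bar."""
        inv = np.linalg.inv(self.basis)
        return (inv @ (np.atleast_2d(x) - self.t).T).T / self.d


def neighbor_pairs(points: np.ndarray, k: int = 4) -> np.ndarray:
    """Ordered pairs (point, one of its k nearest Euclidean neighbours).

    Returns an array of shape (n_pairs, 2, 2); both orientations of a pair
    are retained so the robust statistics run over ordered pairs.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    kk = min(k, len(pts) - 1)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=kk + 1)
    idx = np.atleast_2d(idx)[:, 1:]  # drop self-match
    src = np.repeat(np.arange(len(pts)), kk)
    return np.stack([pts[src], pts[idx.ravel()]], axis=1)


def _trimmed_mean(values: np.ndarray, fraction: float = TRIM_FRACTION) -> float:
    """Mean after discarding the ``fraction`` of values farthest from the median.

    Trimming by distance from the median (rather than a fixed count per
    tail) rejects one-sided contamination: on a square lattice the 4-NN
    pair set unavoidably contains diagonal pairs (length d*sqrt(2), angle
    pi/4) for boundary points — up to ~17% of pairs, all in one tail.
    """
    v = np.asarray(values, dtype=float)
    cut = int(np.ceil(fraction * len(v)))
    if cut >= len(v):
        return float(np.median(v))
    dev = np.abs(v - np.median(v))
    keep = np.argsort(dev, kind="stable")[: len(v) - cut]
    return float(v[keep].mean())


def robust_spacing(pairs: np.ndarray) -> float:
    """30%-trimmed mean of neighbour-pair lengths."""
    lengths = np.linalg.norm(pairs[:, 0] - pairs[:, 1], axis=1)
    return _trimmed_mean(lengths)


def robust_angles(pairs: np.ndarray) -> tuple[float, float]:
    """Principal directions of the deformed grid.

    Pair angles are taken modulo pi into [-pi/4, 3pi/4); angles <= pi/4 feed
    the trimmed mean for alpha_bar (quasi-horizontal class), angles >= pi/4
    the one for beta_bar (quasi-vertical class); pi/4 contributes to both.
    An empty class falls back to the axis-aligned default with a warning.
    """
    vec = pairs[:, 1] - pairs[:, 0]
    ang = np.arctan2(vec[:, 1], vec[:, 0])
    ang = np.mod(ang + np.pi / 4, np.pi) - np.pi / 4  # into [-pi/4, 3pi/4)
    cls_a = ang[ang <= np.pi / 4]
    cls_b = ang[ang >= np.pi / 4]
    if len(cls_a) == 0 or len(cls_b) == 0:
        warnings.warn("empty angle class; falling back to axis-aligned grid")
        return 0.0, np.pi / 2
    return _trimmed_mean(cls_a), _trimmed_mean(cls_b)


def estimate_translation(points: np.ndarray, d: float, alpha: float, beta: float, max_iter: int = 100) -> np.ndarray:
    """Global translation minimizing sum_n min_p ||t + F(p) - x_n||^2.

    Alternates nearest-lattice-node assignment and re-centering until the
    assignment is stable, then folds the result into the fundamental cell
    (the translation is only defined modulo the lattice).
    """
    if abs(np.sin(beta - alpha)) <= 1e-6:
        raise ValueError("degenerate oblique basis")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    grid = ObliqueGrid(d=d, alpha=alpha, beta=beta, t=np.zeros(2))
    t = pts[0].copy()
    prev = None
    for _ in range(max_iter):
        grid.t = t
        p = np.round(grid.array_coords(pts))
        if prev is not None and np.array_equal(p, prev):
            break
        prev = p
        t = np.mean(pts - grid.lattice_map(p), axis=0)
    # fold into the fundamental cell
    grid.t = np.zeros(2)
    q = np.round(np.linalg.inv(grid.basis) @ t / d)
    return t - grid.lattice_map(q)[0]


def estimate_oblique_grid(points: np.ndarray) -> ObliqueGrid:
    """Full affine initialization from observed core centers."""
    pairs = neighbor_pairs(points)
    d = robust_spacing(pairs)
    alpha, beta = robust_angles(pairs)
    t = estimate_translation(points, d, alpha, beta)
    return ObliqueGrid(d=d, alpha=alpha, beta=beta, t=t)


# ---------------------------------------------------------------------------
# thin-plate spline
# ---------------------------------------------------------------------------


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r^2) = r^2 log r^2, with the convention U(0) = 0."""
    out = np.zeros_like(r2, dtype=float)
    mask = r2 > 0
    out[mask] = r2[mask] * np.log(r2[mask])
    return out


@dataclass
class TpsModel:
    """Interpolating map from ideal-grid space to image space.

    ``sources`` are the paired ideal node positions, ``targets`` the paired
    observed centers; ``kernel_coeffs`` (N x 2) and ``affine_coeffs`` (3 x 2,
    rows: constant, x, y) reproduce every target at its source exactly.
    A pure-affine landmark set yields vanishing kernel coefficients and zero
    bending energy.
    """

    sources: np.ndarray
    targets: np.ndarray
    kernel_coeffs: np.ndarray
    affine_coeffs: np.ndarray
    kernel_matrix: np.ndarray = field(repr=False, default=None)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ones = np.ones((len(pts), 1))
        out = np.hstack([ones, pts]) @ self.affine_coeffs
        if len(self.sources):
            d2 = np.sum((pts[:, None, :] - self.sources[None, :, :]) ** 2, axis=-1)
            out = out + _tps_kernel(d2) @ self.kernel_coeffs
        return out

    def bending_energy(self) -> np.ndarray:
        """Standard TPS bending quadratic form w^T K w, per output axis."""
        if not len(self.sources):
            return np.zeros(2)
        return np.einsum("ni,nm,mi->i", self.kernel_coeffs, self.kernel_matrix, self.kernel_coeffs)


def tps_fit(sources: np.ndarray, targets: np.ndarray) -> TpsModel:
    """Fit the interpolating thin-plate spline through landmark pairs.

    Solves the standard bordered system L W = [targets; 0].  Coincident or
    collinear control points make L singular; the pseudo-inverse is used
    then.  With fewer than three pairs the model degenerates to the
    least-squares affine (or pure-translation) map.
    """
    src = np.atleast_2d(np.asarray(sources, dtype=float))
    dst = np.atleast_2d(np.asarray(targets, dtype=float))
    if src.shape != dst.shape:
        raise ValueError("sources and targets must have matching shapes")
    n = len(src)
    if n < 3:
        affine = np.zeros((3, 2))
        if n == 1:
            affine[0] = dst[0] - src[0]
            affine[1:, :] = np.eye(2)
        else:
            shift = np.mean(dst - src, axis=0)
            affine[0] = shift
            affine[1:, :] = np.eye(2)
        return TpsModel(
            sources=np.empty((0, 2)),
            targets=dst,
            kernel_coeffs=np.empty((0, 2)),
            affine_coeffs=affine,
            kernel_matrix=np.empty((0, 0)),
        )
    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    K = _tps_kernel(d2)
    P = np.hstack([np.ones((n, 1)), src])
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(L) @ rhs
    if not np.all(np.isfinite(sol)):
        sol = np.linalg.pinv(L) @ rhs
    return TpsModel(
        sources=src,
        targets=dst,
        kernel_coeffs=sol[:n],
        affine_coeffs=sol[n:],
        kernel_matrix=K,
    )


# ---------------------------------------------------------------------------
# association and iterative registration
# ---------------------------------------------------------------------------


def associate(
    warped_nodes: dict[tuple[int, int], np.ndarray],
    points: np.ndarray,
    delta: float,
) -> list[tuple[int, tuple[int, int]]]:
    """Greedy one-to-one matching of observations to warped grid nodes.

    Candidate pairs within radius delta are taken by increasing distance
    (ties broken by lexicographic node coordinate); every node and every
    observation is used at most once.  Returns (observation index, p) pairs.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    node_ps = list(warped_nodes.keys())
    node_xy = np.array([warped_nodes[p] for p in node_ps])
    if len(node_xy) == 0 or len(pts) == 0:
        return []
    d = np.linalg.norm(pts[:, None, :] - node_xy[None, :, :], axis=-1)
    cand = [
        (d[i, j], node_ps[j], i, j)
        for i in range(len(pts))
        for j in range(len(node_ps))
        if d[i, j] <= delta
    ]
    cand.sort(key=lambda c: (c[0], c[1]))
    used_obs: set[int] = set()
    used_node: set[int] = set()
    out: list[tuple[int, tuple[int, int]]] = []
    for dist, p, i, j in cand:
        if i in used_obs or j in used_node:
            continue
        used_obs.add(i)
        used_node.add(j)
        out.append((i, p))
    return out


def _infer_node_range(grid: ObliqueGrid, points: np.ndarray, pad: int = 0) -> list[tuple[int, int]]:
    """Integer lattice nodes spanned by the observations (bounding box)."""
    p = np.round(grid.array_coords(points)).astype(int)
    k0, k1 = p[:, 1].min() - pad, p[:, 1].max() + pad
    l0, l1 = p[:, 0].min() - pad, p[:, 0].max() + pad
    return [(k, l) for k in range(k0, k1 + 1) for l in range(l0, l1 + 1)]


def register(
    points: np.ndarray,
    oblique: ObliqueGrid,
    d: float | None = None,
    delta: float | None = None,
    max_m: int = 50,
) -> tuple[TpsModel | None, dict[tuple[int, int], np.ndarray], list[tuple[int, tuple[int, int]]], int]:
    """Iteratively fit the TPS deformation of the design grid.

    Starting from the oblique-grid warp, alternate association (radius
    delta, default 0.4*d_bar) and TPS interpolation of the associated pairs,
    re-warping the full node set each iteration, until the maximum node
    displacement drops below tolerance or ``max_m`` iterations.

    Returns (model, warped node map, final associations, iterations used);
    the model is None when the affine initialization was never improved
    (association collapse).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if d is None:
        d = oblique.d  # no design spacing supplied: scale ratio d_bar/d = 1
    if delta is None:
        delta = DELTA_FACTOR * oblique.d
    node_ps = _infer_node_range(oblique, pts)
    ideal = {p: d * np.array([p[1], p[0]], dtype=float) for p in node_ps}  # p=(k,l) -> (x,y)
    scale = oblique.d / d
    warped = {
        p: oblique.t + (scale * oblique.basis @ (d * np.array([p[1], p[0]]))).ravel()
        for p in node_ps
    }
    model: TpsModel | None = None
    pairs: list[tuple[int, tuple[int, int]]] = []
    m = 0
    for m in range(1, max_m + 1):
        pairs = associate(warped, pts, delta)
        if len(pairs) < 3:
            warnings.warn("association collapsed; returning last valid deformation")
            break
        sources = np.array([ideal[p] for _, p in pairs])
        targets = pts[[i for i, _ in pairs]]
        model = tps_fit(sources, targets)
        new_xy = model.evaluate(np.array([ideal[p] for p in node_ps]))
        disp = max(np.linalg.norm(new_xy[k] - warped[p]) for k, p in enumerate(node_ps))
        warped = {p: new_xy[k] for k, p in enumerate(node_ps)}
        if disp < CONVERGENCE_TOL:
            break
    return model, warped, pairs, m


def assign_coordinates(
    points: np.ndarray,
    warped_nodes: dict[tuple[int, int], np.ndarray],
    delta: float,
) -> list[tuple[int, int] | None]:
    """Nearest-warped-node array coordinate for each observation.

    Each observation takes its nearest node; when two observations contend
    for one node the closer wins and the other falls back to its
    next-nearest unclaimed node provided it lies within delta (otherwise it
    stays unassigned).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    node_ps = list(warped_nodes.keys())
    node_xy = np.array([warped_nodes[p] for p in node_ps])
    dmat = np.linalg.norm(pts[:, None, :] - node_xy[None, :, :], axis=-1)
    nearest = dmat.argmin(axis=1)
    order = np.argsort(
        [(dmat[i, nearest[i]]) for i in range(len(pts))]
    )
    cand = []
    for i in range(len(pts)):
        for j in range(len(node_ps)):
            if j == nearest[i] or dmat[i, j] <= delta:
                cand.append((dmat[i, j], i, j))
    cand.sort(key=lambda c: (c[0], node_ps[c[2]]))
    del order
    assigned: list[tuple[int, int] | None] = [None] * len(pts)
    used_node: set[int] = set()
    for dist, i, j in cand:
        if assigned[i] is not None or j in used_node:
            continue
        if dist > delta and j != nearest[i]:
            continue
        assigned[i] = node_ps[j]
        used_node.add(j)
    return assigned


# ---------------------------------------------------------------------------
# result assembly and refinement
# ---------------------------------------------------------------------------


@dataclass
class CoreRecord:
    x: float
    y: float
    p: tuple[int, int] | None
    ellipse: Ellipse | None = None
    provenance: str = "detection"


@dataclass
class DearrayResult:
    cores: list[CoreRecord]
    warped_nodes: dict[tuple[int, int], np.ndarray]
    oblique: ObliqueGrid
    tps: TpsModel | None
    iterations: int = 0

    @property
    def extent(self) -> tuple[tuple[int, int], tuple[int, int]] | None:
        ps = [c.p for c in self.cores if c.p is not None]
        if not ps:
            return None
        ks = [p[0] for p in ps]
        ls = [p[1] for p in ps]
        return (min(ks), max(ks)), (min(ls), max(ls))

    def summary(self) -> dict:
        bend = self.tps.bending_energy() if self.tps is not None else np.zeros(2)
        return {
            "n_cores": len(self.cores),
            "n_assigned": sum(c.p is not None for c in self.cores),
            "spacing": self.oblique.d,
            "alpha_rad": self.oblique.alpha,
            "beta_rad": self.oblique.beta,
            "translation": list(map(float, self.oblique.t)),
            "iterations": self.iterations,
            "bending_energy_x": float(bend[0]),
            "bending_energy_y": float(bend[1]),
        }


def refine(
    img: IntensityImage,
    result: DearrayResult,
    fit_cfg: FitConfig,
    d: float | None = None,
    delta: float | None = None,
) -> DearrayResult:
    """Second segmentation pass at grid nodes left without a core.

    Each empty node seeds an ellipse fit (center = node, radius r_core);
    fits passing the size/roundness screen are appended with provenance
    "refinement", the TPS is refit once with the augmented landmark set, and
    coordinates are re-assigned on the updated grid.
    """
    if delta is None:
        delta = DELTA_FACTOR * result.oblique.d
    if d is None:
        d = result.oblique.d
    occupied = {c.p for c in result.cores if c.p is not None}
    empty = [p for p in result.warped_nodes if p not in occupied]
    existing = [(c.x, c.y) for c in result.cores]
    new_cores: list[CoreRecord] = []
    for p in empty:
        x, y = result.warped_nodes[p]
        if not (0 <= x <= img.width - 1 and 0 <= y <= img.height - 1):
            continue
        patch = extract_patch(img, (x, y), fit_cfg.rho)
        init = Ellipse(x, y, fit_cfg.r_core, fit_cfg.r_core, 0.0)
        fr: FitResult = fit_single(patch, init, fit_cfg, provenance="refinement")
        if not fr.accepted:
            continue
        ex, ey = fr.ellipse.x0, fr.ellipse.y0
        if any(np.hypot(ex - ox, ey - oy) <= fit_cfg.min_center_sep for ox, oy in existing):
            continue
        existing.append((ex, ey))
        new_cores.append(CoreRecord(x=ex, y=ey, p=p, ellipse=fr.ellipse, provenance="refinement"))
    if not new_cores and result.tps is not None:
        return result
    # refit the spline once with the augmented pair list
    all_cores = result.cores + new_cores
    paired = [(c, c.p) for c in all_cores if c.p is not None]
    if len(paired) >= 3:
        sources = np.array([[d * p[1], d * p[0]] for _, p in paired])
        targets = np.array([[c.x, c.y] for c, _ in paired])
        model = tps_fit(sources, targets)
        node_ps = list(result.warped_nodes.keys())
        xy = model.evaluate(np.array([[d * p[1], d * p[0]] for p in node_ps]))
        warped = {p: xy[k] for k, p in enumerate(node_ps)}
    else:
        model, warped = result.tps, result.warped_nodes
    pts = np.array([[c.x, c.y] for c in all_cores])
    assigned = assign_coordinates(pts, warped, delta)
    for c, p in zip(all_cores, assigned):
        c.p = p
    return DearrayResult(
        cores=all_cores,
        warped_nodes=warped,
        oblique=result.oblique,
        tps=model,
        iterations=result.iterations,
    )
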