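"""Ellipse-shaped active contours for core segmentation.

Each detected position seeds a pair of concentric, coaxial ellipses: an outer
ellipse Gamma with parameters {x0, a, b, theta} and an inner ellipse Gamma'
with axes a/sqrt(2), b/sqrt(2), so |Gamma| = 2|Gamma'| and the elliptical
ring and the inner core have equal areas.  The energy is the normalized
contrast between ring and core,

    J(u, Gamma) = (1/ab) * sum_x  w_eps(||x - x0||_Gamma^2) * u[x],

where ||.||_Gamma is the ellipse-induced quadratic norm and w_eps is a smooth
(logistic) surrogate of the indicator pattern (+1 on the ring, -2 extra on
the core, i.e. 1_Gamma - 2*1_Gamma'): on a constant image the two domains
cancel and J = 0, while a bright core inside Gamma' drives J negative.
Minimizing J over the five parameters with analytic gradients fits one
ellipse per patch; the problem is separable across patches apart from a
pairwise non-overlap constraint which is enforced post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .io_preprocess import IntensityImage, Patch, extract_patch

__all__ = [
    "Ellipse",
    "FitConfig",
    "FitResult",
    "ellipse_norm2",
    "logistic_weight",
    "logistic_weight_deriv",
    "ellipse_energy",
    "ellipse_energy_gradient",
    "fit_single",
    "fit_all",
]


@dataclass
class Ellipse:
    """Outer ellipse {x0, a, b, theta}; the inner ellipse shares the center
    and orientation with axes divided by sqrt(2)."""

    x0: float
    y0: float
    a: float
    b: float
    theta: float

    def normalized(self) -> "Ellipse":
        """Return an equivalent ellipse with a >= b and theta in [-pi/2, pi/2)."""
        a, b, th = self.a, self.b, self.theta
        if b > a:
            a, b = b, a
            th = th + np.pi / 2
        th = (th + np.pi / 2) % np.pi - np.pi / 2
        return Ellipse(self.x0, self.y0, a, b, th)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0, self.y0)

    def as_vector(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.a, self.b, self.theta])


@dataclass
class FitConfig:
    """Active-contour configuration.

    eps
        Logistic steepness in normalized-metric units; 0.05 gives a soft
        boundary about one pixel wide for r_core >= 10 px.
    r_core, rho
        Expected core radius and patch radius (rho defaults to 2*r_core).
    rho_max, r_min, r_max, theta_min, theta_max
        Box constraints of the optimizer: center excursion, axis range and
        orientation range.
    screen_lo, screen_hi, elongation_max
        Acceptance screen on the *outer* ellipse: the outer axes of a
        perfectly round core of radius r_core are sqrt(2)*r_core, so the
        band is symmetric around that value; flattened fits with
        a/b > elongation_max are discarded ("tiny, giant and flattened").
    min_center_sep
        Two accepted ellipses closer than this keep only the lower energy
        one (non-overlap constraint, = rho).
    """

    r_core: float = 15.0
    eps: float = 0.05
    rho: float | None = None
    rho_max: float | None = None
    r_min: float | None = None
    r_max: float | None = None
    theta_min: float = -np.pi / 2
    theta_max: float = np.pi / 2
    elongation_max: float = 2.0
    screen_lo: float | None = None
    screen_hi: float | None = None
    min_center_sep: float | None = None
    max_iter: int = 200
    gtol: float = 1e-6

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        r = self.r_core
        if self.rho_max is None:
            self.rho_max = 0.5 * r
        if self.r_min is None:
            self.r_min = 0.5 * r
        if self.r_max is None:
            self.r_max = 2.2 * r
        if self.rho is None:
            # the patch must contain every admissible ellipse: the energy's
            # ring/core cancellation breaks when the outer ring is clipped,
            # biasing fits outward on bright backgrounds
            self.rho = self.rho_max + self.r_max
        if self.r_min >= self.r_max:
            raise ValueError("r_min must be below r_max")
        outer = np.sqrt(2.0) * r
        if self.screen_lo is None:
            self.screen_lo = 0.75 * outer
        if self.screen_hi is None:
            self.screen_hi = 1.5 * outer
        if self.min_center_sep is None:
            self.min_center_sep = self.rho


@dataclass
class FitResult:
    ellipse: Ellipse
    energy: float
    converged: bool
    accepted: bool
    provenance: str = "detection"  # or "refinement"


def ellipse_norm2(x: np.ndarray, y: np.ndarray, e: Ellipse) -> np.ndarray:
    """Squared ellipse-induced norm ||x - x0||_Gamma^2.

    Rotation by theta aligns the major axis with the horizontal, then the
    coordinates are scaled by (1/a, 1/b); the value is <= 1 iff the point
    lies inside Gamma.
    """
    dx = np.asarray(x, dtype=float) - e.x0
    dy = np.asarray(y, dtype=float) - e.y0
    c, s = np.cos(e.theta), np.sin(e.theta)
    u1 = (c * dx + s * dy) / e.a
    u2 = (-s * dx + c * dy) / e.b
    return u1 * u1 + u2 * u2


def logistic_weight(t: np.ndarray | float, eps: float) -> np.ndarray | float:
    """w_eps(t) = S_eps(t) - 2 S_eps(2t) with S_eps(t) = 1/(1+exp((t-1)/eps)).

    As eps -> 0 this converges pointwise to +1 on the ring (0.5 < t < 1)
    and -1 on the core (t < 0.5), vanishing outside the outer ellipse.
    Evaluated through expit for overflow safety.
    """
    t = np.asarray(t, dtype=float)
    return expit(-(t - 1.0) / eps) - 2.0 * expit(-(2.0 * t - 1.0) / eps)


def logistic_weight_deriv(t: np.ndarray | float, eps: float) -> np.ndarray | float:
    """w'_eps(t) = [4 S(2t)(1-S(2t)) - S(t)(1-S(t))] / eps."""
    t = np.asarray(t, dtype=float)
    s1 = expit(-(t - 1.0) / eps)
    s2 = expit(-(2.0 * t - 1.0) / eps)
    return (4.0 * s2 * (1.0 - s2) - s1 * (1.0 - s1)) / eps


def ellipse_energy(patch: Patch, e: Ellipse, eps: float) -> float:
    """Contrast energy J over the valid pixels of the patch."""
    xx, yy = patch.grid()
    t = ellipse_norm2(xx, yy, e)
    return float(np.sum(logistic_weight(t, eps) * patch.pixels) / (e.a * e.b))


def ellipse_energy_gradient(patch: Patch, e: Ellipse, eps: float) -> np.ndarray:
    """Analytic gradient of J w.r.t. (x0, y0, a, b, theta).

    Only pixels near the two ellipse boundaries contribute (w' vanishes
    elsewhere); the axis derivatives carry the extra -J/a and -J/b terms
    from the 1/(ab) normalization.
    """
    xx, yy = patch.grid()
    dx = xx - e.x0
    dy = yy - e.y0
    c, s = np.cos(e.theta), np.sin(e.theta)
    u1 = (c * dx + s * dy) / e.a
    u2 = (-s * dx + c * dy) / e.b
    t = u1 * u1 + u2 * u2
    w = logistic_weight(t, eps)
    wp = logistic_weight_deriv(t, eps)
    inv_ab = 1.0 / (e.a * e.b)
    J = float(np.sum(w * patch.pixels) * inv_ab)
    uwp = patch.pixels * wp
    # partials of t = ||x - x0||_Gamma^2
    dt_dx0 = -2.0 * (u1 * c / e.a - u2 * s / e.b)
    dt_dy0 = -2.0 * (u1 * s / e.a + u2 * c / e.b)
    dt_da = -2.0 * u1 * u1 / e.a
    dt_db = -2.0 * u2 * u2 / e.b
    dt_dth = 2.0 * u1 * u2 * (e.b / e.a - e.a / e.b)
    g_x0 = inv_ab * float(np.sum(uwp * dt_dx0))
    g_y0 = inv_ab * float(np.sum(uwp * dt_dy0))
    g_a = inv_ab * float(np.sum(uwp * dt_da)) - J / e.a
    g_b = inv_ab * float(np.sum(uwp * dt_db)) - J / e.b
    g_th = inv_ab * float(np.sum(uwp * dt_dth))
    return np.array([g_x0, g_y0, g_a, g_b, g_th])


def fit_single(
    patch: Patch,
    init: Ellipse,
    cfg: FitConfig,
    provenance: str = "detection",
) -> FitResult:
    """Minimize J from the given initial ellipse under box constraints.

    The center may move at most rho_max (per coordinate) from the *initial*
    center, the axes stay within [r_min, r_max] and the rotation within
    [theta_min, theta_max].  After convergence a >= b is re-imposed by an
    axis swap plus a pi/2 shift of theta, and the size/roundness screen sets
    the ``accepted`` flag.
    """
    cx, cy = init.x0, init.y0
    xx, yy = patch.grid()

    def objective(v: np.ndarray) -> tuple[float, np.ndarray]:
        e = Ellipse(*v)
        grad = ellipse_energy_gradient(patch, e, cfg.eps)
        t = ellipse_norm2(xx, yy, e)
        J = float(np.sum(logistic_weight(t, cfg.eps) * patch.pixels) / (e.a * e.b))
        if not np.isfinite(J):
            raise FloatingPointError("non-finite ellipse energy")
        return J, grad

    bounds = [
        (cx - cfg.rho_max, cx + cfg.rho_max),
        (cy - cfg.rho_max, cy + cfg.rho_max),
        (cfg.r_min, cfg.r_max),
        (cfg.r_min, cfg.r_max),
        (cfg.theta_min, cfg.theta_max),
    ]
    res = minimize(
        objective,
        init.as_vector(),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": cfg.max_iter, "gtol": cfg.gtol, "ftol": 1e-12},
    )
    e = Ellipse(*res.x).normalized()
    accepted = (
        cfg.screen_lo <= e.b
        and e.a <= cfg.screen_hi
        and e.a / e.b <= cfg.elongation_max
    )
    return FitResult(
        ellipse=e,
        energy=float(res.fun),
        converged=bool(res.success),
        accepted=bool(accepted),
        provenance=provenance,
    )


def fit_all(
    img: IntensityImage,
    centroids: Sequence[tuple[float, float]],
    cfg: FitConfig,
    provenance: str = "detection",
) -> list[FitResult]:
    """Fit one ellipse per candidate patch, then resolve overlaps.

    Each patch is optimized independently (the joint energy is separable);
    afterwards any pair of *accepted* ellipses whose centers are closer than
    ``min_center_sep`` keeps only the lower-energy one.
    """
    results: list[FitResult] = []
    for c in centroids:
        patch = extract_patch(img, c, cfg.rho)
        init = Ellipse(c[0], c[1], cfg.r_core, cfg.r_core, 0.0)
        results.append(fit_single(patch, init, cfg, provenance=provenance))
    # pairwise non-overlap: keep the deeper minimum
    order = np.argsort([r.energy for r in results])
    kept_centers: list[tuple[float, float]] = []
    for idx in order:
        r = results[idx]
        if not r.accepted:
            continue
        x, y = r.ellipse.x0, r.ellipse.y0
        if any(np.hypot(x - kx, y - ky) <= cfg.min_center_sep for kx, ky in kept_centers):
            r.accepted = False
        else:
            kept_centers.append((x, y))
    return results
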