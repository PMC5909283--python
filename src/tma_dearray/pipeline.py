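"""End-to-end de-arraying pipeline.

Wires detection, optional ellipse segmentation, grid registration, optional
refinement and coordinate assignment, under the four workflow options:

====== ============== ===================
option segmentation   non-linear warp
====== ============== ===================
1      off            off (affine only)
2      on             off (affine only)
3      off            on  (TPS)
4      on             on  (TPS)
====== ============== ===================

With segmentation off, localization is the raw wavelet centroids (no
size/roundness screen, and no refinement pass, which needs segmentation).
With the non-linear stage off, the deformation is the oblique (affine) grid
and coordinates come from the nearest oblique node.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ellipse_fit import FitConfig, fit_all
from .grid_register import (
    CoreRecord,
    DearrayResult,
    DELTA_FACTOR,
    _infer_node_range,
    assign_coordinates,
    estimate_oblique_grid,
    refine,
    register,
)
from .io_preprocess import IntensityImage, invert_if_dark_objects
from .wavelet_detect import WaveletConfig, detect_cores

__all__ = ["PipelineConfig", "PipelineError", "run_dearray", "result_to_dataframe", "OPTION_FLAGS"]

OPTION_FLAGS = {1: (False, False), 2: (True, False), 3: (False, True), 4: (True, True)}


class PipelineError(RuntimeError):
    """Raised when the pipeline cannot produce a result (e.g. no detections)."""


@dataclass
class PipelineConfig:
    """All pipeline parameters with their documented defaults."""

    r_core: float = 15.0
    sigma1: float = 2.0
    p_fa: float = 0.05
    eps: float = 0.05
    delta_factor: float = DELTA_FACTOR
    d: float | None = None  # design spacing; default: estimated d_bar
    rows: int | None = None
    cols: int | None = None
    segmentation_on: bool = False
    nonlinear_on: bool = True
    max_m: int = 50
    seed: int = 0

    @classmethod
    def from_option(cls, option: int, **kwargs) -> "PipelineConfig":
        seg, nl = OPTION_FLAGS[option]
        return cls(segmentation_on=seg, nonlinear_on=nl, **kwargs)

    def as_dict(self) -> dict:
        return asdict(self)


def run_dearray(img: IntensityImage, cfg: PipelineConfig) -> DearrayResult:
    """Run detection -> (segmentation) -> registration -> (refinement)."""
    img = invert_if_dark_objects(img)
    wcfg = WaveletConfig(r_core=cfg.r_core, sigma1=cfg.sigma1, p_fa=cfg.p_fa)
    centroids, _, _ = detect_cores(img, wcfg)
    if not centroids:
        raise PipelineError("no candidate cores detected")

    fit_cfg = FitConfig(r_core=cfg.r_core, eps=cfg.eps)
    cores: list[CoreRecord]
    if cfg.segmentation_on:
        fits = fit_all(img, centroids, fit_cfg)
        cores = [
            CoreRecord(x=f.ellipse.x0, y=f.ellipse.y0, p=None, ellipse=f.ellipse)
            for f in fits
            if f.accepted
        ]
        if not cores:
            raise PipelineError("all candidates rejected by the segmentation screen")
    else:
        cores = [CoreRecord(x=c[0], y=c[1], p=None) for c in centroids]

    pts = np.array([[c.x, c.y] for c in cores])
    oblique = estimate_oblique_grid(pts)
    delta = cfg.delta_factor * oblique.d

    if cfg.nonlinear_on:
        model, warped, _, iterations = register(
            pts, oblique, d=cfg.d, delta=delta, max_m=cfg.max_m
        )
    else:
        node_ps = _infer_node_range(oblique, pts)
        warped = {p: oblique.affine_map(np.array([p[1], p[0]], dtype=float))[0] for p in node_ps}
        model, iterations = None, 0

    assigned = assign_coordinates(pts, warped, delta)
    for c, p in zip(cores, assigned):
        c.p = p
    result = DearrayResult(
        cores=cores, warped_nodes=warped, oblique=oblique, tps=model, iterations=iterations
    )
    if cfg.segmentation_on and cfg.nonlinear_on:
        result = refine(img, result, fit_cfg, d=cfg.d, delta=delta)
    return result


def result_to_dataframe(result: DearrayResult) -> pd.DataFrame:
    """Flat per-core table (k, l, x, y, a, b, theta_rad, provenance)."""
    rows = []
    for c in result.cores:
        e = c.ellipse
        rows.append(
            {
                "k": c.p[0] if c.p is not None else None,
                "l": c.p[1] if c.p is not None else None,
                "x": c.x,
                "y": c.y,
                "a": e.a if e else np.nan,
                "b": e.b if e else np.nan,
                "theta_rad": e.theta if e else np.nan,
                "provenance": c.provenance,
            }
        )
    return pd.DataFrame(rows)
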