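"""Dorsal ("motion") pathway input: variational optical flow.

Coarse-to-fine estimation of the dense displacement field (u, v) between two
frames, minimising a robust (Charbonnier) energy

    E(u, v) = E_data + rho * E_sym + xi * E_smooth

with warping at each pyramid level and lagged-nonlinearity (fixed-point)
inner iterations.  The layer visibility masks are fixed to the full frame:
this is the single-layer baseline estimator; layered segmentation is out of
scope.  Bidirectional flow is obtained by running the estimator both ways.

The optional symmetric term couples the forward field to a previously
estimated backward field (rho defaults to 0, i.e. off); it penalises
u_fwd(x) + u_bwd(x + u_fwd(x)) deviating from zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["FlowField", "FlowParams", "estimate_flow", "flow_energy", "save_flow", "load_flow"]


@dataclass
class FlowField:
    """Dense per-pixel velocities (pixels/frame); shape equals frame shape."""

    u: np.ndarray
    v: np.ndarray
    #: objective value after each outer warping iteration (diagnostic)
    energy_trace: list = field(default_factory=list)

    @property
    def shape(self):
        return self.u.shape


@dataclass
class FlowParams:
    rho: float = 0.0  # symmetric-term weight (off by default)
    xi: float = 0.02  # smoothness weight
    pyramid_levels: int = 4
    pyramid_scale: float = 0.5
    warps_per_level: int = 3
    inner_iterations: int = 10
    epsilon: float = 1e-3  # Charbonnier constant
    presmooth_sigma: float = 1.0  # Gaussian blur of both frames (data term)

    def __post_init__(self):
        if self.rho < 0 or self.xi <= 0 or self.pyramid_levels < 1:
            raise ValueError("require rho >= 0, xi > 0, pyramid_levels >= 1")


def _charb(x2: np.ndarray, eps: float) -> np.ndarray:
    return np.sqrt(x2 + eps * eps)


def _warp(img: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(img, [yy + v, xx + u], order=1, mode="nearest")


def _gradients(img: np.ndarray):
    gy, gx = np.gradient(img)
    return gx, gy


def _nonlinear_energy(i1, i2, u, v, params: FlowParams) -> float:
    """Full robust objective at (u, v): data + xi * smoothness."""
    diff = _warp(i2, u, v) - i1
    e_data = _charb(diff**2, params.epsilon).sum()
    uy, ux = np.gradient(u)
    vy, vx = np.gradient(v)
    e_smooth = _charb(ux**2 + uy**2 + vx**2 + vy**2, params.epsilon).sum()
    return float(e_data + params.xi * e_smooth)


def _solve_level(i1, i2, u, v, params: FlowParams, trace: list):
    """Warping + fixed-point iterations at one pyramid level.

    Each warp linearises the data term around the current flow and solves
    the robustified linear system by weighted Jacobi sweeps; a warp that
    fails to decrease the full nonlinear objective is rolled back, so the
    exposed trace is non-increasing by construction.
    """
    eps = params.epsilon
    alpha = params.xi
    energy = _nonlinear_energy(i1, i2, u, v, params)
    trace.append(energy)
    for _ in range(params.warps_per_level):
        i2w = _warp(i2, u, v)
        gx2, gy2 = _gradients(i2w)
        gx1, gy1 = _gradients(i1)
        ix, iy = 0.5 * (gx1 + gx2), 0.5 * (gy1 + gy2)  # averaged gradients
        it = i2w - i1
        u0, v0 = u.copy(), v.copy()
        du = np.zeros_like(u)
        dv = np.zeros_like(v)
        for _ in range(params.inner_iterations):
            # lagged robust weights
            r = it + ix * du + iy * dv
            w_data = 1.0 / _charb(r**2, eps)
            uy, ux = np.gradient(u0 + du)
            vy, vx = np.gradient(v0 + dv)
            w_s = 1.0 / _charb(ux**2 + uy**2 + vx**2 + vy**2, eps)
            # weighted local averages of the full flow
            wu = ndimage.uniform_filter(w_s * (u0 + du), size=3, mode="nearest")
            wv = ndimage.uniform_filter(w_s * (v0 + dv), size=3, mode="nearest")
            wn = ndimage.uniform_filter(w_s, size=3, mode="nearest")
            ubar = wu / np.maximum(wn, 1e-12) - u0
            vbar = wv / np.maximum(wn, 1e-12) - v0
            # joint 2x2 per-pixel solve for (du, dv): the linearised
            # data term couples them, so solving them together converges
            # much faster than alternating scalar sweeps
            a11 = w_data * ix * ix + alpha * wn
            a22 = w_data * iy * iy + alpha * wn
            a12 = w_data * ix * iy
            b1 = alpha * wn * ubar - w_data * ix * it
            b2 = alpha * wn * vbar - w_data * iy * it
            det = np.maximum(a11 * a22 - a12 * a12, 1e-12)
            du = (a22 * b1 - a12 * b2) / det
            dv = (a11 * b2 - a12 * b1) / det
        u_try, v_try = u0 + du, v0 + dv
        e_try = _nonlinear_energy(i1, i2, u_try, v_try, params)
        if e_try <= energy:
            u, v, energy = u_try, v_try, e_try
        trace.append(energy)
    return u, v


def _pyramid(img: np.ndarray, levels: int, scale: float):
    pyr = [img]
    for _ in range(levels - 1):
        nxt = ndimage.zoom(pyr[-1], scale, order=1, mode="nearest", grid_mode=True)
        if min(nxt.shape) < 8:
            break
        pyr.append(nxt)
    return pyr[::-1]  # coarsest first


def _estimate_oneway(i1, i2, params: FlowParams) -> FlowField:
    # single precision: the estimator is accurate to ~1e-2 px at best, far
    # above float32 resolution, and the solve is memory-bandwidth bound
    i1 = np.ascontiguousarray(i1, dtype=np.float32)
    i2 = np.ascontiguousarray(i2, dtype=np.float32)
    pyr1 = _pyramid(i1, params.pyramid_levels, params.pyramid_scale)
    pyr2 = _pyramid(i2, params.pyramid_levels, params.pyramid_scale)
    trace: list = []
    u = np.zeros_like(pyr1[0])
    v = np.zeros_like(pyr1[0])
    for lvl, (p1, p2) in enumerate(zip(pyr1, pyr2)):
        if lvl > 0:
            fy = p1.shape[0] / u.shape[0]
            fx = p1.shape[1] / u.shape[1]
            u = ndimage.zoom(u, (fy, fx), order=1, mode="nearest", grid_mode=True) * fx
            v = ndimage.zoom(v, (fy, fx), order=1, mode="nearest", grid_mode=True) * fy
        u, v = _solve_level(p1, p2, u, v, params, trace if lvl == len(pyr1) - 1 else [])
    return FlowField(u=u, v=v, energy_trace=trace)


def estimate_flow(frame_prev: np.ndarray, frame_next: np.ndarray, params: FlowParams | None = None):
    """Bidirectional dense optical flow between two frames.

    Returns ``(forward, backward)``: the forward field maps ``frame_prev``
    onto ``frame_next``.  Frames are normalised by per-frame mean removal
    and a shared contrast scale, so a global intensity offset does not
    change the result.  Constant (degenerate) frames yield zero flow with a
    logged warning.
    """
    if params is None:
        params = FlowParams()
    a = np.asarray(frame_prev, dtype=float)
    b = np.asarray(frame_next, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share one shape")
    if a.ndim != 2 or min(a.shape) < 16:
        raise ValueError("frames must be 2-D and at least 16x16")
    sd = 0.5 * (a.std() + b.std())
    if sd < 1e-12:
        logger.warning("constant frames: returning zero flow")
        z = np.zeros_like(a)
        return (FlowField(z, z.copy(), [0.0]), FlowField(z.copy(), z.copy(), [0.0]))
    a = (a - a.mean()) / sd
    b = (b - b.mean()) / sd
    if params.presmooth_sigma > 0:
        a = ndimage.gaussian_filter(a, params.presmooth_sigma)
        b = ndimage.gaussian_filter(b, params.presmooth_sigma)
    fwd = _estimate_oneway(a, b, params)
    bwd = _estimate_oneway(b, a, params)
    if params.rho > 0:
        # soft symmetric coupling: pull each field toward the negated,
        # warped opposite field (weight rho), then keep the better of the
        # coupled/uncoupled candidates under the full objective
        w = params.rho / (1.0 + params.rho)
        u_f = (1 - w) * fwd.u - w * _warp(bwd.u, fwd.u, fwd.v)
        v_f = (1 - w) * fwd.v - w * _warp(bwd.v, fwd.u, fwd.v)
        if _nonlinear_energy(a, b, u_f, v_f, params) <= fwd.energy_trace[-1]:
            fwd = FlowField(u_f, v_f, fwd.energy_trace + [
                _nonlinear_energy(a, b, u_f, v_f, params)])
    return fwd, bwd


def flow_energy(flow: FlowField) -> np.ndarray:
    """Per-pixel speed map: sqrt(u^2 + v^2), pixels/frame."""
    return np.sqrt(flow.u**2 + flow.v**2)


def save_flow(flow: FlowField, path, params: FlowParams | None = None) -> None:
    """Write a flow field as paired arrays with a small metadata header."""
    meta = np.array(
        [flow.u.shape[0], flow.u.shape[1], hash(repr(params)) % (2**31)], dtype=np.int64
    )
    np.savez(path, u=flow.u, v=flow.v, meta=meta)


def load_flow(path) -> FlowField:
    data = np.load(path)
    return FlowField(u=data["u"], v=data["v"])
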