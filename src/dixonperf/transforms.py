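"""Rigid 2D transforms and image resampling helpers.

Conventions used throughout the package:

* a rigid transform ``p = (tx, ty, theta)`` maps a point ``x`` (in
  ``(y, x)`` pixel coordinates) to ``T_p(x) = R(theta) (x - c) + c + t``
  where ``c`` is the rotation centre and ``t = (ty, tx)``;
* ``warp_rigid(I, p)`` resamples ``I`` at ``T_p(x)``, i.e. it *pulls*
  intensities from the transformed location.  Registering a moving image
  to a reference therefore returns the parameters of the content
  displacement of the moving image relative to the reference;
* sequential warps compose as
  ``warp(warp(I, p), q) == warp(I, compose(p, q))`` with
  ``T_compose(p, q) = T_p ∘ T_q``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "rigid_matrix", "params_from_matrix", "compose_rigid", "invert_rigid",
    "warp_rigid", "warp_dense",
]


def rigid_matrix(params, center) -> np.ndarray:
    """Homogeneous 3x3 matrix of ``T_p`` acting on (y, x, 1) columns."""
    tx, ty, theta = params
    cy, cx = center
    c, s = np.cos(theta), np.sin(theta)
    r = np.array([[c, -s], [s, c]])
    cvec = np.array([cy, cx])
    t = np.array([ty, tx])
    m = np.eye(3)
    m[:2, :2] = r
    m[:2, 2] = cvec - r @ cvec + t
    return m


def params_from_matrix(m: np.ndarray, center) -> tuple:
    """Recover ``(tx, ty, theta)`` from a rigid homogeneous matrix."""
    theta = float(np.arctan2(m[1, 0], m[0, 0]))
    cy, cx = center
    cvec = np.array([cy, cx])
    t = m[:2, 2] - cvec + m[:2, :2] @ cvec
    return float(t[1]), float(t[0]), theta


def compose_rigid(p, q, center) -> tuple:
    """Parameters of ``T_p ∘ T_q`` (apply-warp order: first p, then q)."""
    m = rigid_matrix(p, center) @ rigid_matrix(q, center)
    return params_from_matrix(m, center)


def invert_rigid(p, center) -> tuple:
    m = np.linalg.inv(rigid_matrix(p, center))
    return params_from_matrix(m, center)


def _sample(image: np.ndarray, coords, order: int, mode: str, cval: float):
    if np.iscomplexobj(image):
        re = ndimage.map_coordinates(image.real, coords, order=order, mode=mode, cval=cval)
        im = ndimage.map_coordinates(image.imag, coords, order=order, mode=mode, cval=cval)
        return re + 1j * im
    return ndimage.map_coordinates(image, coords, order=order, mode=mode, cval=cval)


def warp_rigid(image: np.ndarray, params, center=None, order: int = 1,
               mode: str = "nearest", cval: float = 0.0) -> np.ndarray:
    """Resample ``image`` under the rigid transform ``params``.

    ``order=0`` gives nearest-neighbour (exact for integer shifts),
    ``order=1`` bilinear.  ``mode`` controls out-of-grid padding.
    """
    ny, nx = image.shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    m = rigid_matrix(params, center)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel(), np.ones(ny * nx)])
    src = m @ pts
    coords = src[:2].reshape(2, ny, nx)
    return _sample(image, coords, order, mode, cval)


def warp_dense(image: np.ndarray, dy: np.ndarray, dx: np.ndarray,
               order: int = 1, mode: str = "nearest", cval: float = 0.0) -> np.ndarray:
    """Resample ``image`` at ``(y + dy, x + dx)`` (pull-back of the field)."""
    ny, nx = image.shape
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    return _sample(image, [yy + dy, xx + dx], order, mode, cval)
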