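"""Multi-echo Dixon water–fat separation.

Chemical-shift encoding: at echo time ``TE_n`` the complex signal of a
pixel containing water ``W`` and single-peak fat ``F`` (off-resonance
``Δf_fat``, −434 Hz at 3 T) in a background field ``ψ`` (Hz) is::

    s_n = (W + F e^(i 2π Δf_fat TE_n)) e^(i 2π ψ TE_n)

Given ``ψ``, the model is linear in (W, F) and solved per pixel by
complex least squares over the echoes.  The field map can be estimated
per frame by a variable-projection residual search over candidate ``ψ``
followed by spatial smoothing.

Water images carry the contrast enhancement (the diagnostic series);
fat images are unaffected by gadolinium and drive the rigid motion
estimation.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .series import DynamicEchoSeries, WaterFatPair

__all__ = ["separate_water_fat", "estimate_field_map", "DegenerateEncodingError"]


class DegenerateEncodingError(ValueError):
    """Echo times do not encode water and fat independently."""


def _encoding_matrix(echo_times_ms: np.ndarray, fat_offset_hz: float) -> np.ndarray:
    te_s = np.asarray(echo_times_ms, float) * 1e-3
    a = np.column_stack([np.ones_like(te_s, dtype=complex),
                         np.exp(1j * 2 * np.pi * fat_offset_hz * te_s)])
    # all echoes in-phase (fat phasor identical on every echo) -> rank 1
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise DegenerateEncodingError(
            "echo times leave water and fat in phase; separation is ill-posed")
    return a


def separate_water_fat(series: DynamicEchoSeries, fat_offset: float = -434.0,
                       field_map_mode: str = "none",
                       field_map: Optional[Union[float, np.ndarray]] = None,
                       smoothing_sigma: float = 3.0) -> WaterFatPair:
    """Separate a dynamic multi-echo series into water and fat magnitudes.

    Parameters
    ----------
    series : DynamicEchoSeries
        Complex data for any field-map handling; magnitude-only input is
        accepted for ``field_map_mode='none'`` on real-valued data only in
        the trivial sense of treating it as zero-phase complex.
    fat_offset : float
        Fat chemical-shift off-resonance in Hz.
    field_map_mode : {'none', 'fixed', 'estimate'}
        'none' fixes ψ = 0; 'fixed' uses the supplied ``field_map`` (Hz,
        scalar or per-pixel); 'estimate' runs :func:`estimate_field_map`
        per frame.
    """
    if field_map_mode not in ("none", "fixed", "estimate"):
        raise ValueError(f"unknown field_map_mode {field_map_mode!r}")
    a = _encoding_matrix(series.echo_times, fat_offset)
    pinv = np.linalg.pinv(a)                       # (2, n_echoes)
    te_s = series.echo_times * 1e-3
    data = series.data.astype(complex)
    nt, ne, ny, nx = data.shape

    if field_map_mode == "none":
        psi_t = np.zeros((nt, ny, nx))
    elif field_map_mode == "fixed":
        if field_map is None:
            raise ValueError("field_map_mode='fixed' requires a field_map")
        psi = np.asarray(field_map, float)
        psi = np.broadcast_to(psi, (ny, nx))
        psi_t = np.broadcast_to(psi, (nt, ny, nx))
    else:
        if not series.is_complex:
            raise ValueError("field-map estimation requires complex data")
        psi_t = np.stack([
            estimate_field_map(data[t], series.echo_times, fat_offset,
                               smoothing_sigma=smoothing_sigma)
            for t in range(nt)
        ])

    water = np.empty((nt, ny, nx))
    fat = np.empty((nt, ny, nx))
    for t in range(nt):
        demod = data[t] * np.exp(-1j * 2 * np.pi * psi_t[t][None] * te_s[:, None, None])
        wf = np.tensordot(pinv, demod, axes=(1, 0))   # (2, ny, nx)
        water[t] = np.abs(wf[0])
        fat[t] = np.abs(wf[1])
    fmap = psi_t if field_map_mode != "none" else None
    return WaterFatPair(water=water, fat=fat, frame_times=series.frame_times.copy(),
                        field_map=fmap, pixel_spacing=series.pixel_spacing)


def estimate_field_map(frame: np.ndarray, echo_times_ms: np.ndarray,
                       fat_offset: float = -434.0, smoothing_sigma: float = 3.0,
                       step_hz: float = 1.0) -> np.ndarray:
    """Estimate the per-pixel off-resonance ψ (Hz) of one multi-echo frame.

    Variable projection: for each candidate ψ on a grid spanning the
    unambiguous range ±1/(2 ΔTE), the (W, F) pair is projected out and the
    per-pixel residual recorded; the argmin map is then Gaussian-smoothed
    (σ in pixels).  Requires complex data and at least three echoes.
    """
    frame = np.asarray(frame)
    if not np.iscomplexobj(frame):
        raise ValueError("field-map estimation requires complex data")
    if frame.shape[0] < 3:
        raise ValueError("field-map estimation requires at least three echoes")
    te_s = np.asarray(echo_times_ms, float) * 1e-3
    a = _encoding_matrix(echo_times_ms, fat_offset)
    # orthogonal projector onto the complement of the water/fat subspace
    proj = np.eye(len(te_s), dtype=complex) - a @ np.linalg.pinv(a)

    dte = np.diff(te_s).mean()
    psi_max = 1.0 / (2.0 * dte)
    cands = np.arange(-psi_max, psi_max + step_hz, step_hz)
    ne, ny, nx = frame.shape
    pix = frame.reshape(ne, -1)
    best_res = np.full(pix.shape[1], np.inf)
    best_psi = np.zeros(pix.shape[1])
    for psi in cands:
        demod = pix * np.exp(-1j * 2 * np.pi * psi * te_s)[:, None]
        res = np.sum(np.abs(proj @ demod) ** 2, axis=0)
        better = res < best_res
        best_res[better] = res[better]
        best_psi[better] = psi
    psi_map = best_psi.reshape(ny, nx)
    # pure-fat pixels admit a swapped solution at psi + fat_offset; snap each
    # pixel's estimate to the alias closest to the bright-pixel consensus
    mag = np.abs(frame).sum(axis=0)
    bright = mag > 0.5 * np.median(mag[mag > 0]) if np.any(mag > 0) else mag > -1
    consensus = np.median(psi_map[bright]) if bright.any() else 0.0
    alias = abs(fat_offset)
    if alias > 0:
        k = np.round((psi_map - consensus) / alias)
        psi_map = psi_map - k * alias
    if smoothing_sigma > 0:
        # magnitude-weighted smoothing keeps noise-only pixels from biasing tissue
        w = np.abs(frame).sum(axis=0)
        w = w / (w.max() + 1e-30) + 1e-6
        psi_map = ndimage.gaussian_filter(psi_map * w, smoothing_sigma) / \
            ndimage.gaussian_filter(w, smoothing_sigma)
    return psi_map
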