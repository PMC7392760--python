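"""In-memory containers for dynamic multi-echo cardiac MRI series.

The acquisition this package targets is a saturation-recovery spoiled
gradient-echo readout that collects several echoes per excitation, one
2D frame per heart beat.  The raw object is therefore a 4D stack indexed
``(time, echo, y, x)``; after water–fat separation it becomes a pair of
3D stacks ``(time, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["DynamicEchoSeries", "WaterFatPair"]


@dataclass
class DynamicEchoSeries:
    """A dynamic multi-echo image series.

    Parameters
    ----------
    data : ndarray, shape (n_frames, n_echoes, ny, nx)
        Complex or magnitude images.  One spatial slice; frames are the
        dynamic (per-heart-beat) dimension.
    echo_times : ndarray, shape (n_echoes,)
        Echo times in milliseconds, strictly increasing.
    frame_times : ndarray, shape (n_frames,)
        Acquisition time of each frame in seconds, strictly increasing.
    pixel_spacing : float
        In-plane pixel spacing in millimetres.
    """

    data: np.ndarray
    echo_times: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: float = 2.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be 4D (time, echo, y, x); got shape {self.data.shape}"
            )
        nt, ne = self.data.shape[:2]
        if ne < 2:
            raise ValueError("at least two echoes are required")
        if self.echo_times.shape != (ne,):
            raise ValueError(
                f"echo_times has {self.echo_times.size} entries but data has {ne} echoes"
            )
        if self.frame_times.shape != (nt,):
            raise ValueError(
                f"frame_times has {self.frame_times.size} entries but data has {nt} frames"
            )
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if not np.all(np.isfinite(self.data.view(float) if np.iscomplexobj(self.data) else self.data)):
            raise ValueError("data contains NaN or inf")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)

    def magnitude(self) -> "DynamicEchoSeries":
        """Return a magnitude copy of the series."""
        return DynamicEchoSeries(
            np.abs(self.data), self.echo_times.copy(), self.frame_times.copy(),
            self.pixel_spacing,
        )


@dataclass
class WaterFatPair:
    """Dixon-separated dynamic water and fat magnitude series.

    ``water`` is the diagnostic series (carries the contrast enhancement),
    ``fat`` the registration series (static during the bolus).  Both are
    ``(time, y, x)`` and non-negative.
    """

    water: np.ndarray
    fat: np.ndarray
    frame_times: np.ndarray = field(default=None)  # type: ignore[assignment]
    field_map: Optional[np.ndarray] = None  # Hz, per frame or single map
    pixel_spacing: float = 2.5

    def __post_init__(self) -> None:
        self.water = np.asarray(self.water, dtype=float)
        self.fat = np.asarray(self.fat, dtype=float)
        if self.water.shape != self.fat.shape:
            raise ValueError("water and fat stacks must have identical shapes")
        if self.water.ndim != 3:
            raise ValueError("water/fat stacks must be 3D (time, y, x)")
        if np.any(self.water < 0) or np.any(self.fat < 0):
            raise ValueError("water and fat magnitudes must be non-negative")
        if self.frame_times is None:
            self.frame_times = np.arange(self.water.shape[0], dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.water.shape[0],):
                raise ValueError("frame_times length must match the number of frames")

    @property
    def n_frames(self) -> int:
        return self.water.shape[0]
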