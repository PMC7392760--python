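"""NIfTI / CSV / JSON readers and writers.

Interchange conventions:

* dynamic multi-echo series: one 5D NIfTI ``(x, y, 1, time, echo)`` or
  one 4D file per echo ``(x, y, 1, time)``, complex64 or float32, plus a
  JSON sidecar (:class:`SeriesMeta`) carrying timing and acquisition
  parameters;
* masks: NIfTI unsigned-integer label images ``(x, y, 1)``;
* curves: CSV with a ``time_s`` column and one column per curve.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .series import DynamicEchoSeries

__all__ = ["SeriesMeta", "read_series", "write_series", "read_mask",
           "write_mask", "read_curves", "write_curves"]


@dataclass
class SeriesMeta:
    """Sidecar metadata for a dynamic multi-echo series."""

    echo_times: List[float]            # ms
    frame_times: List[float]           # s
    flip_angle: float = 14.0           # deg
    saturation_delay: float = 75.0     # ms
    pixel_spacing: float = 2.5         # mm
    dilution: float = 0.1
    hct: float = 0.42
    fat_offset: float = -434.0         # Hz

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SeriesMeta":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def _to_nifti_array(data: np.ndarray) -> np.ndarray:
    """(t, e, y, x) -> (x, y, 1, t, e)"""
    return np.transpose(data, (3, 2, 0, 1))[:, :, None, :, :]


def _from_nifti_array(arr: np.ndarray) -> np.ndarray:
    """(x, y, 1, t, e) -> (t, e, y, x)"""
    return np.transpose(arr[:, :, 0, :, :], (2, 3, 1, 0))


def write_series(series: DynamicEchoSeries, path: Union[str, Path],
                 meta_path: Optional[Union[str, Path]] = None,
                 layout: str = "5d", **meta_kwargs) -> None:
    """Write a series as 5D NIfTI (or one 4D file per echo) plus metadata.

    With ``layout='4d-per-echo'`` the path is used as a template and
    ``_e1``, ``_e2``, … are appended before the extension.
    """
    path = Path(path)
    dtype = np.complex64 if series.is_complex else np.float32
    affine = np.diag([series.pixel_spacing, series.pixel_spacing, 10.0, 1.0])
    if layout == "5d":
        arr = _to_nifti_array(series.data).astype(dtype)
        nib.save(nib.Nifti1Image(arr, affine), str(path))
    elif layout == "4d-per-echo":
        stem, suffix = _split_nii_name(path)
        for e in range(series.n_echoes):
            arr = _to_nifti_array(series.data[:, e:e + 1]).astype(dtype)[:, :, :, :, 0]
            nib.save(nib.Nifti1Image(arr, affine), str(path.parent / f"{stem}_e{e + 1}{suffix}"))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if meta_path is not None:
        SeriesMeta(echo_times=list(map(float, series.echo_times)),
                   frame_times=list(map(float, series.frame_times)),
                   pixel_spacing=series.pixel_spacing, **meta_kwargs).to_json(meta_path)


def _split_nii_name(path: Path):
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)], suffix
    return path.stem, path.suffix


def read_series(path: Union[str, Path, Sequence[Union[str, Path]]],
                meta_path: Union[str, Path]) -> DynamicEchoSeries:
    """Read a 5D series (single path) or a 4D-per-echo triplet (list of
    paths, echo order) and validate it against its metadata sidecar."""
    meta = SeriesMeta.from_json(meta_path)
    if isinstance(path, (str, Path)):
        arr = np.asanyarray(nib.load(str(path)).dataobj)
        if arr.ndim != 5:
            raise ValueError(f"expected a 5D NIfTI (x, y, z, time, echo); got {arr.ndim}D")
        data = _from_nifti_array(arr)
    else:
        echoes = [np.asanyarray(nib.load(str(p)).dataobj) for p in path]
        for e, a in enumerate(echoes):
            if a.ndim != 4:
                raise ValueError(f"echo file {e + 1} is {a.ndim}D; expected 4D (x, y, z, time)")
        stacked = np.stack(echoes, axis=-1)            # (x, y, 1, t, e)
        data = _from_nifti_array(stacked)
    ne = data.shape[1]
    nt = data.shape[0]
    if len(meta.echo_times) != ne:
        raise ValueError(
            f"metadata lists {len(meta.echo_times)} echo times but the file has {ne} echoes")
    if len(meta.frame_times) != nt:
        raise ValueError(
            f"metadata lists {len(meta.frame_times)} frame times but the file has {nt} frames")
    return DynamicEchoSeries(data, np.array(meta.echo_times), np.array(meta.frame_times),
                             meta.pixel_spacing)


def write_mask(mask: np.ndarray, path: Union[str, Path], pixel_spacing: float = 2.5) -> None:
    arr = np.asarray(mask).astype(np.uint8).T[:, :, None]
    affine = np.diag([pixel_spacing, pixel_spacing, 10.0, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_mask(path: Union[str, Path]) -> np.ndarray:
    arr = np.asanyarray(nib.load(str(path)).dataobj)
    return arr[:, :, 0].T.astype(np.uint8)


def write_curves(path: Union[str, Path], time_s: np.ndarray, **curves) -> None:
    df = pd.DataFrame({"time_s": np.asarray(time_s, float)})
    for name, vals in curves.items():
        df[name] = np.asarray(vals, float)
    df.to_csv(path, index=False)


def read_curves(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)
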