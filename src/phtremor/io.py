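"""File formats: NIfTI volumes, delimited traces, matrices and ledgers.

Volumes go through NIfTI-1 (nibabel); the repetition time is stored in
the header (pixdim[4] with time units of seconds) and voxel sizes in the
zooms.  Atlas label names travel in a YAML sidecar next to the image
(``<path>.labels.yaml``) because NIfTI has no label-table field.
Physiological traces are 2-column delimited text (time_s, value) with a
single header line; matrices are TSV with ROI-name headers.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import AccelTrace, AtlasVolume, Bold4D, SessionEvents

__all__ = [
    "write_volume",
    "write_statmap",
    "read_statmap",
    "read_bold",
    "read_atlas",
    "read_volume",
    "write_trace",
    "read_trace",
    "write_accel_trace",
    "read_accel_trace",
    "write_matrix",
    "read_matrix",
    "write_truth_ledger",
    "read_truth_ledger",
]


def _sidecar(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return p.with_name(name + ".labels.yaml")


def write_volume(obj: Bold4D | AtlasVolume, path) -> None:
    path = Path(path)
    if isinstance(obj, Bold4D):
        affine = np.diag(list(obj.voxel_size_mm) + [1.0])
        img = nib.Nifti1Image(obj.data.astype(np.float64), affine)
        img.header.set_zooms(tuple(obj.voxel_size_mm) + (obj.tr_s,))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))
    elif isinstance(obj, AtlasVolume):
        affine = np.diag(list(obj.voxel_size_mm) + [1.0])
        img = nib.Nifti1Image(obj.labels.astype(np.int32), affine)
        img.header.set_zooms(tuple(obj.voxel_size_mm))
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
        with open(_sidecar(path), "w") as fh:
            yaml.safe_dump({int(k): str(v) for k, v in obj.label_table.items()}, fh)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_bold(path) -> Bold4D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return Bold4D(data.astype(float), tr_s=tr, voxel_size_mm=tuple(zooms[:3]))


def read_atlas(path) -> AtlasVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: atlas must be 3D, got ndim={data.ndim}")
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: atlas must be integer-labelled")
    labels = np.round(data).astype(np.int32)
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            table = {int(k): str(v) for k, v in yaml.safe_load(fh).items()}
    else:
        table = {int(k): f"roi_{int(k)}" for k in np.unique(labels) if k != 0}
    zooms = img.header.get_zooms()
    return AtlasVolume(labels=labels, voxel_size_mm=tuple(zooms[:3]),
                       label_table=table)


def write_statmap(stat_map, path) -> None:
    """Write a 3D statistical map as NIfTI (kind is not persisted)."""
    affine = np.diag(list(stat_map.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(stat_map.values.astype(np.float64), affine)
    img.header.set_zooms(tuple(stat_map.voxel_size_mm))
    nib.save(img, str(path))


def read_statmap(path, kind: str = "beta", df: int | None = None):
    from .types import StatMap

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    return StatMap(data.astype(float), kind, df=df, voxel_size_mm=tuple(zooms[:3]))


def read_volume(path) -> Bold4D | AtlasVolume:
    """Dispatch on dimensionality: 4D -> Bold4D, 3D integer -> AtlasVolume."""
    img = nib.load(str(path))
    ndim = len(img.shape)
    if ndim == 4:
        return read_bold(path)
    if ndim == 3:
        return read_atlas(path)
    raise ValueError(f"{path}: unsupported image dimensionality {ndim}")


def write_trace(times_s: np.ndarray, values: np.ndarray, path,
                value_name: str = "value") -> None:
    df = pd.DataFrame({"time_s": np.asarray(times_s, float),
                       value_name: np.asarray(values, float)})
    df.to_csv(path, index=False)


def read_trace(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 2-column (time_s, value) delimited file; times must increase."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    times = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(float)
    values = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    return times, values


def write_accel_trace(trace: AccelTrace, path) -> None:
    write_trace(trace.times(), trace.samples, path, value_name="accel")
    if trace.events is not None:
        meta = {
            "rate_hz": trace.rate_hz,
            "baseline_start_s": trace.events.baseline_start_s,
            "injection_s": trace.events.injection_s,
            "end_s": trace.events.end_s,
        }
        with open(str(path) + ".events.json", "w") as fh:
            json.dump(meta, fh)


def read_accel_trace(path, rate_hz: float | None = None,
                     injection_s: float | None = None) -> AccelTrace:
    times, values = read_trace(path)
    dt = np.diff(times)
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(dt))
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: accelerometer trace must be uniformly sampled")
    events = None
    meta_path = Path(str(path) + ".events.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        events = SessionEvents(meta["baseline_start_s"], meta["injection_s"],
                               meta["end_s"])
    elif injection_s is not None:
        events = SessionEvents(times[0], injection_s, times[-1] + dt[0])
    return AccelTrace(samples=values, rate_hz=float(rate_hz),
                      t0_s=float(times[0]), events=events)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth_ledger(ledger: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ledger, fh, sort_keys=False)


def read_truth_ledger(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
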