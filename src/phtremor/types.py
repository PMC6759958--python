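"""Core in-memory containers shared across the pipeline.

All images are plain numpy arrays with a small amount of geometry metadata
(voxel size in mm, repetition time in seconds).  Coordinates are reported
as millimetre offsets from the volume centre, so a label volume and a BOLD
volume on the same grid are directly comparable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Bold4D",
    "AtlasVolume",
    "AccelTrace",
    "SessionEvents",
    "StatMap",
    "RoiTimeSeries",
]


@dataclass
class Bold4D:
    """A 4D BOLD series: three spatial axes by time.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Signal values; float.
    tr_s : float
        Repetition time (volume spacing) in seconds.
    voxel_size_mm : sequence of 3 floats
        Voxel edge lengths in millimetres.
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: tuple[float, float, float] = (1.7, 1.7, 2.4)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Bold4D requires a 4D array, got ndim={self.data.ndim}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def frame_times(self) -> np.ndarray:
        """Onset time of each volume in seconds (0, TR, 2 TR, ...)."""
        return np.arange(self.n_volumes) * self.tr_s

    def copy_with(self, data: np.ndarray) -> "Bold4D":
        return Bold4D(data=data, tr_s=self.tr_s, voxel_size_mm=self.voxel_size_mm)


@dataclass
class AtlasVolume:
    """3D integer label image mapping voxels to named regions of interest.

    Label 0 is background; every nonzero label present in ``labels`` must
    appear in ``label_table``.
    """

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.7, 1.7, 2.4)
    label_table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.label_table = dict(self.label_table)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_table")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def roi_names(self) -> list[str]:
        return [self.label_table[k] for k in sorted(self.label_table)]

    def label_of(self, name: str) -> int:
        for lab, nm in self.label_table.items():
            if nm == name:
                return lab
        raise KeyError(f"ROI {name!r} not in atlas")

    def roi_mask(self, name: str) -> np.ndarray:
        """Boolean mask of the voxels belonging to the named ROI."""
        mask = self.labels == self.label_of(name)
        if not mask.any():
            raise ValueError(f"ROI {name!r} is empty in this atlas")
        return mask

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class SessionEvents:
    """Timing landmarks of a behavioural session, in trace seconds."""

    baseline_start_s: float
    injection_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (self.baseline_start_s <= self.injection_s <= self.end_s):
            raise ValueError("events must be ordered: baseline_start <= injection <= end")


@dataclass
class AccelTrace:
    """Uniformly sampled single-channel acceleration magnitude signal."""

    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    events: SessionEvents | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("accelerometer samples must be 1D")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("accelerometer samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.rate_hz


VALID_MAP_KINDS = ("beta", "t", "p", "psc", "slope")


@dataclass
class StatMap:
    """A 3D statistical map (betas, t-values, p-values or percent change).

    ``degenerate`` flags voxels where the statistic was undefined (zero
    residual variance, zero baseline); values there are reported as 0 (or 1
    for p-maps) rather than inf/nan.
    """

    values: np.ndarray
    kind: str
    df: int | None = None
    voxel_size_mm: tuple[float, float, float] = (1.7, 1.7, 2.4)
    degenerate: np.ndarray | None = None
    threshold_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be 3D")
        if self.kind not in VALID_MAP_KINDS:
            raise ValueError(f"kind must be one of {VALID_MAP_KINDS}")
        if self.kind == "p":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("p-map values must lie in [0, 1]")
        if self.kind == "t" and self.df is not None and self.df < 1:
            raise ValueError("t-map requires df >= 1")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.degenerate is not None:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class RoiTimeSeries:
    """ROI-mean BOLD time series: one row per named ROI."""

    data: np.ndarray  # (n_rois, n_volumes)
    roi_names: Sequence[str]
    tr_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RoiTimeSeries data must be 2D (rois x volumes)")
        self.roi_names = list(self.roi_names)
        if len(self.roi_names) != self.data.shape[0]:
            raise ValueError("one name per row required")
        if np.isnan(self.data).any():
            raise ValueError("RoiTimeSeries must not contain missing values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def index_of(self, name: str) -> int:
        return list(self.roi_names).index(name)

    def frame_times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_volumes) * self.tr_s
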