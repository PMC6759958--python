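"""Hemodynamic response model and GLM design construction.

The drug response is modelled as a single boxcar of configurable length
starting at the injection onset, convolved with a canonical double-gamma
hemodynamic response function and peak-normalised to 1.  The species-
specific HRF is unknown, so human-canonical parameters (peak delay 5 s,
undershoot delay 15 s, undershoot ratio 1/6) are the defaults and fully
exposed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["HrfParams", "hrf", "TaskDesign", "build_design"]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters (all in seconds except the ratio)."""

    peak_delay_s: float = 5.0
    peak_dispersion_s: float = 1.0
    undershoot_delay_s: float = 15.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        for name in ("peak_delay_s", "peak_dispersion_s",
                     "undershoot_delay_s", "undershoot_dispersion_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be non-negative")


def hrf(t, params: HrfParams | None = None) -> np.ndarray:
    """Canonical double-gamma response at times ``t`` (seconds).

    Zero for t <= 0.  Shape a and scale of each gamma are chosen so the
    mode of the positive lobe sits at ``peak_delay_s`` and the undershoot
    mode at ``undershoot_delay_s``.  The returned curve is normalised to
    unit peak on the evaluation grid of a dense internal reference, so the
    function is deterministic in t.
    """
    params = params or HrfParams()
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    def _raw(tt: np.ndarray) -> np.ndarray:
        a1 = params.peak_delay_s / params.peak_dispersion_s + 1.0
        a2 = params.undershoot_delay_s / params.undershoot_dispersion_s + 1.0
        pos = gamma_dist.pdf(tt, a1, scale=params.peak_dispersion_s)
        neg = gamma_dist.pdf(tt, a2, scale=params.undershoot_dispersion_s)
        out = pos - params.undershoot_ratio * neg
        out[tt <= 0] = 0.0
        return out

    # normalise by the peak on a dense reference grid
    ref = _raw(np.arange(0.0, params.undershoot_delay_s * 3, 0.001))
    peak = ref.max()
    if peak <= 0:
        raise ValueError("degenerate HRF parameters: non-positive peak")
    out = _raw(t) / peak
    return float(out[0]) if scalar else out


@dataclass
class TaskDesign:
    """GLM design matrix with a labelled task column.

    The task regressor is zero before the injection onset and
    peak-normalised to 1; intercept and linear-drift columns are appended,
    followed by any extra confound columns (e.g. the heart-rate
    regressor, so the activation fit is a joint model).
    """

    matrix: np.ndarray
    column_names: list[str]
    tr_s: float
    onset_s: float
    block_length_s: float
    hrf_params: HrfParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if len(self.column_names) != self.matrix.shape[1]:
            raise ValueError("one name per design column required")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def task_index(self) -> int:
        return self.column_names.index("task")

    @property
    def regressor(self) -> np.ndarray:
        return self.matrix[:, self.task_index]


def build_design(
    n_volumes: int,
    tr_s: float,
    onset_s: float,
    block_length_s: float,
    hrf_params: HrfParams | None = None,
    *,
    drift: bool = True,
    confounds: dict[str, np.ndarray] | None = None,
    oversample: int = 20,
    impulse_hrf: bool = False,
) -> TaskDesign:
    """Build the injection-block GLM design.

    A boxcar of ``block_length_s`` seconds starting at ``onset_s`` is
    convolved with the HRF on a grid of ``tr_s / oversample`` seconds,
    sampled at volume onsets and peak-normalised.  ``impulse_hrf=True``
    replaces the HRF with a discrete unit impulse, so the task column is
    the boxcar itself (useful for validation).
    """
    if n_volumes < 2:
        raise ValueError("need at least two volumes")
    if block_length_s <= 0:
        raise ValueError("block_length_s must be positive")
    duration = n_volumes * tr_s
    if not (0 <= onset_s < duration):
        raise ValueError("onset_s outside the scan")
    if onset_s + block_length_s > duration:
        raise ValueError("block extends past the end of the scan")

    dt = tr_s / oversample
    grid = np.arange(0.0, duration, dt)
    boxcar = ((grid >= onset_s) & (grid < onset_s + block_length_s)).astype(float)
    if impulse_hrf:
        kernel = np.zeros(1)
        kernel[0] = 1.0
    else:
        kernel_t = np.arange(0.0, 50.0, dt)
        kernel = hrf(kernel_t, hrf_params)
    conv = np.convolve(boxcar, kernel)[: grid.size]
    task = conv[::oversample][:n_volumes].copy()
    peak = np.abs(task).max()
    if peak <= 0:
        raise ValueError("task regressor is identically zero at volume times")
    task /= task.max()

    cols = [task]
    names = ["task"]
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    if drift:
        d = np.linspace(-1.0, 1.0, n_volumes)
        cols.append(d)
        names.append("drift")
    for nm, col in (confounds or {}).items():
        col = np.asarray(col, dtype=float)
        if col.shape != (n_volumes,):
            raise ValueError(f"confound {nm!r} must have length {n_volumes}")
        cols.append(col)
        names.append(nm)

    return TaskDesign(
        matrix=np.column_stack(cols),
        column_names=names,
        tr_s=tr_s,
        onset_s=onset_s,
        block_length_s=block_length_s,
        hrf_params=hrf_params,
        meta={"oversample": oversample, "impulse_hrf": impulse_hrf},
    )
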