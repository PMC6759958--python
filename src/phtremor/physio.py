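"""Cardiovascular artifact removal by heart-rate nuisance regression.

Intravenous drug injection produces a pronounced bradycardia whose time
course leaks into the global BOLD signal.  The correction regresses each
voxel series on the continuously recorded heart-rate waveform (linearly
interpolated to volume onset times, standardised, optionally lagged by an
integer number of volumes) together with an intercept and a linear drift
column, and keeps the residual with its mean level re-added so percent
signal change remains computable downstream.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Bold4D

__all__ = [
    "DegenerateRegressorError",
    "NuisanceDesign",
    "resample_to_volumes",
    "build_nuisance_design",
    "NuisanceRegression",
    "NuisanceRegressionResults",
    "regress_nuisance",
]


class DegenerateRegressorError(ValueError):
    """The nuisance trace carries no variance at the volume times."""


def resample_to_volumes(
    times_s: np.ndarray,
    values: np.ndarray,
    n_volumes: int,
    tr_s: float,
    *,
    center: bool = True,
    scale: bool = True,
    lag_volumes: int = 0,
) -> np.ndarray:
    """Interpolate a physiological trace at volume onset times.

    The trace must span the scan (first onset to last onset).  After
    linear interpolation the regressor is mean-centred and scaled to unit
    standard deviation (both optional).  ``lag_volumes`` shifts the
    regressor forward by whole volumes (edge values held), for the case
    where the BOLD drift trails the heart-rate change.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_s.size < 2:
        raise ValueError("need at least two trace points")
    if times_s.shape != values.shape:
        raise ValueError("times and values must have equal length")
    onsets = np.arange(n_volumes) * tr_s
    eps = 1e-9
    if times_s[0] > onsets[0] + eps or times_s[-1] < onsets[-1] - eps:
        raise ValueError(
            f"trace [{times_s[0]:g}, {times_s[-1]:g}] s does not cover the "
            f"scan [{onsets[0]:g}, {onsets[-1]:g}] s"
        )
    reg = np.interp(onsets, times_s, values)
    if lag_volumes:
        reg = np.roll(reg, lag_volumes)
        if lag_volumes > 0:
            reg[:lag_volumes] = reg[lag_volumes]
        else:
            reg[lag_volumes:] = reg[lag_volumes - 1]
    if center:
        reg = reg - reg.mean()
    if scale:
        sd = reg.std()
        if sd <= 1e-12 * max(1.0, np.abs(values).max()):
            raise DegenerateRegressorError(
                "heart-rate regressor has zero variance at volume times"
            )
        reg = reg / sd
    return reg


@dataclass
class NuisanceDesign:
    """Nuisance design: intercept, optional linear drift, heart-rate column."""

    matrix: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("nuisance design must be 2D")
        if len(self.column_names) != self.matrix.shape[1]:
            raise ValueError("one name per column required")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("nuisance design is rank deficient")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def build_nuisance_design(
    hr_regressor: np.ndarray, *, drift: bool = True
) -> NuisanceDesign:
    hr = np.asarray(hr_regressor, dtype=float)
    n = hr.size
    cols = [np.ones(n)]
    names = ["intercept"]
    if drift:
        cols.append(np.linspace(-1.0, 1.0, n))
        names.append("drift")
    cols.append(hr)
    names.append("heart_rate")
    return NuisanceDesign(np.column_stack(cols), names)


class NuisanceRegression:
    """Voxelwise OLS of a BOLD series on a nuisance design."""

    def __init__(self, bold: Bold4D, design: NuisanceDesign):
        if design.n_volumes != bold.n_volumes:
            raise ValueError("design row count must equal volume count")
        self.bold = bold
        self.design = design

    def fit(self) -> "NuisanceRegressionResults":
        X = self.design.matrix
        n = X.shape[0]
        Y = self.bold.data.reshape(-1, n).T
        if not np.all(np.isfinite(Y)):
            raise ValueError("BOLD series contains non-finite values")
        pinv = np.linalg.pinv(X)
        betas = pinv @ Y
        fitted = X @ betas
        resid = Y - fitted
        # re-add the intercept contribution so the residual series keeps
        # its mean level (percent signal change needs it)
        i0 = self.design.column_names.index("intercept")
        resid_with_mean = resid + np.outer(X[:, i0], betas[i0])
        grid = self.bold.grid_shape
        return NuisanceRegressionResults(
            residual=self.bold.copy_with(resid_with_mean.T.reshape(grid + (n,))),
            fitted_artifact=self.bold.copy_with(fitted.T.reshape(grid + (n,))),
            betas=betas.reshape((X.shape[1],) + grid),
            design=self.design,
        )


@dataclass
class NuisanceRegressionResults:
    residual: Bold4D
    fitted_artifact: Bold4D
    betas: np.ndarray
    design: NuisanceDesign

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, nm in enumerate(self.design.column_names):
            b = self.betas[i]
            rows.append({"column": nm, "mean_beta": float(b.mean()),
                         "sd_beta": float(b.std())})
        return pd.DataFrame(rows)


def regress_nuisance(bold: Bold4D, design: NuisanceDesign) -> tuple[Bold4D, Bold4D]:
    """Convenience wrapper returning (residual, fitted artifact)."""
    res = NuisanceRegression(bold, design).fit()
    return res.residual, res.fitted_artifact
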