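"""Voxelwise regression of activation betas on tremor severity.

Each drug fMRI session contributes a beta map; the interleaved
behavioural session with the same ordinal position contributes the
animal's maximum normalised tremor index.  Observations are pooled
across animals and sessions by default (a per-animal fit is exposed for
sensitivity checks) and each voxel's beta is regressed on the tremor
index by simple least squares; the slope, its t and two-sided p are
reported, conventionally thresholded at uncorrected p < 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import StatMap

__all__ = ["BetaTremorRegression", "BetaTremorResults", "regress_beta_on_tremor"]

_VAR_EPS = 1e-12


@dataclass
class BetaTremorObservation:
    animal: str
    session: int
    beta_map: StatMap
    max_tremor_index: float


class BetaTremorRegression:
    """Simple linear model beta_v = a_v + b_v * tremor, per voxel.

    Parameters
    ----------
    beta_maps : list of StatMap
        One per (animal, session) observation, congruent grids.
    tremor_indices : sequence of float
        Matched maximum tremor indices.
    """

    def __init__(self, beta_maps: list[StatMap], tremor_indices):
        if len(beta_maps) != len(list(tremor_indices)):
            raise ValueError("one tremor index per beta map required")
        if len(beta_maps) < 3:
            raise ValueError("need at least three observations")
        grid = beta_maps[0].grid_shape
        for m in beta_maps[1:]:
            if m.grid_shape != grid:
                raise ValueError("beta maps must share a grid")
        x = np.asarray(list(tremor_indices), dtype=float)
        if x.std() <= 1e-12 * max(1.0, np.abs(x).max()):
            raise ValueError("tremor index is constant across observations")
        self.beta_maps = beta_maps
        self.x = x

    def fit(self) -> "BetaTremorResults":
        grid = self.beta_maps[0].grid_shape
        vs = self.beta_maps[0].voxel_size_mm
        Y = np.stack([m.values.reshape(-1) for m in self.beta_maps])  # (n, V)
        x = self.x
        n = x.size
        xc = x - x.mean()
        sxx = float(xc @ xc)
        slope = (xc @ Y) / sxx
        intercept = Y.mean(axis=0) - slope * x.mean()
        fitted = np.outer(x, slope) + intercept
        resid = Y - fitted
        df = n - 2
        ss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = ss / df
        scale = np.maximum(np.einsum("ij,ij->j", Y, Y) / n, 1.0)
        degen = sigma2 <= _VAR_EPS * scale
        se = np.sqrt(np.maximum(sigma2, 0.0) / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(degen, 0.0, slope / np.where(se > 0, se, np.inf))
        p = np.where(degen, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
        return BetaTremorResults(
            slope_map=StatMap(slope.reshape(grid), "slope", df=df, voxel_size_mm=vs,
                              degenerate=degen.reshape(grid)),
            t_map=StatMap(t.reshape(grid), "t", df=df, voxel_size_mm=vs,
                          degenerate=degen.reshape(grid)),
            p_map=StatMap(p.reshape(grid), "p", df=df, voxel_size_mm=vs),
            df=df,
            n_obs=n,
        )


@dataclass
class BetaTremorResults:
    slope_map: StatMap
    t_map: StatMap
    p_map: StatMap
    df: int
    n_obs: int

    def suprathreshold_mask(self, p: float = 0.05, positive_only: bool = False) -> np.ndarray:
        mask = self.p_map.values < p
        if positive_only:
            mask &= self.slope_map.values > 0
        return mask

    def enrichment_odds_ratio(self, roi_mask: np.ndarray, p: float = 0.05,
                              brain_mask: np.ndarray | None = None) -> float:
        """Odds ratio of suprathreshold voxels inside vs outside a target
        ROI set (Haldane 0.5 correction for empty cells)."""
        supra = self.suprathreshold_mask(p)
        roi_mask = np.asarray(roi_mask, dtype=bool)
        domain = np.ones_like(roi_mask) if brain_mask is None else \
            np.asarray(brain_mask, dtype=bool)
        a = float(np.sum(supra & roi_mask & domain))
        b = float(np.sum(~supra & roi_mask & domain))
        c = float(np.sum(supra & ~roi_mask & domain))
        d = float(np.sum(~supra & ~roi_mask & domain))
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a / b) / (c / d)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": ["n_obs", "df", "max_t", "min_p",
                             "n_suprathreshold_p05"],
                "value": [self.n_obs, self.df,
                          float(self.t_map.values.max()),
                          float(self.p_map.values.min()),
                          int(self.suprathreshold_mask().sum())],
            }
        )


def regress_beta_on_tremor(
    beta_maps: list[StatMap], tremor_indices
) -> tuple[StatMap, StatMap, StatMap]:
    """Convenience wrapper returning (slope, t, p) maps."""
    res = BetaTremorRegression(beta_maps, tremor_indices).fit()
    return res.slope_map, res.t_map, res.p_map
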