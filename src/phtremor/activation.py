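"""Voxelwise GLM activation mapping and map-level statistics.

The model is ordinary least squares of each voxel's BOLD series on a
:class:`~phtremor.design.TaskDesign`; the statistic of interest is the
task beta (percent signal change per unit regressor when fitted to
percent-signal-change data) and its t-value.  Group maps are one-sample
or paired t-tests across per-session beta maps, thresholded either with
Benjamini–Hochberg FDR (group map, q < 0.0005) or an uncorrected p
threshold (per-session paired maps, p < 0.005).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .design import TaskDesign, build_design, HrfParams
from .types import AtlasVolume, Bold4D, StatMap

__all__ = [
    "VoxelGLM",
    "VoxelGLMResults",
    "fit_glm",
    "percent_signal_change",
    "smooth_gaussian",
    "group_one_sample_t",
    "paired_t",
    "fdr_threshold",
    "block_length_sweep",
    "cluster_peaks",
    "PEAK_TABLE_COLUMNS",
]

_VAR_EPS = 1e-12


class VoxelGLM:
    """Massively univariate OLS of a BOLD series on a task design.

    Parameters
    ----------
    bold : Bold4D
        The (artifact-corrected, typically percent-signal-change) series.
    design : TaskDesign
        Design matrix; its row count must equal the number of volumes.
    """

    def __init__(self, bold: Bold4D, design: TaskDesign):
        if design.n_volumes != bold.n_volumes:
            raise ValueError(
                f"design has {design.n_volumes} rows but bold has "
                f"{bold.n_volumes} volumes"
            )
        self.bold = bold
        self.design = design

    def fit(self) -> "VoxelGLMResults":
        X = self.design.matrix
        n, k = X.shape
        rank = np.linalg.matrix_rank(X)
        if rank < k:
            raise ValueError("design matrix is rank deficient")
        df = n - rank
        if df < 1:
            raise ValueError("no residual degrees of freedom")

        grid = self.bold.grid_shape
        Y = self.bold.data.reshape(-1, n).T  # (n, V)
        if not np.all(np.isfinite(Y)):
            raise ValueError("BOLD series contains non-finite values")
        xtx_inv = np.linalg.inv(X.T @ X)
        betas = xtx_inv @ (X.T @ Y)  # (k, V)
        resid = Y - X @ betas
        ss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = ss / df

        j = self.design.task_index
        cjj = xtx_inv[j, j]
        se = np.sqrt(np.maximum(sigma2, 0.0) * cjj)
        scale = np.maximum(np.einsum("ij,ij->j", Y, Y) / n, 1.0)
        degen = sigma2 <= _VAR_EPS * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(degen, 0.0, betas[j] / np.where(se > 0, se, np.inf))
        pvals = np.where(degen, 1.0, 2.0 * stats.t.sf(np.abs(tvals), df))

        vs = self.bold.voxel_size_mm
        return VoxelGLMResults(
            beta_map=StatMap(betas[j].reshape(grid), "beta", df=df, voxel_size_mm=vs),
            t_map=StatMap(tvals.reshape(grid), "t", df=df, voxel_size_mm=vs,
                          degenerate=degen.reshape(grid)),
            p_map=StatMap(pvals.reshape(grid), "p", df=df, voxel_size_mm=vs),
            df=df,
            design=self.design,
            all_betas=betas.reshape((k,) + grid),
            sigma2=sigma2.reshape(grid),
        )


@dataclass
class VoxelGLMResults:
    """Per-voxel task beta, t and p maps from a :class:`VoxelGLM` fit."""

    beta_map: StatMap
    t_map: StatMap
    p_map: StatMap
    df: int
    design: TaskDesign
    all_betas: np.ndarray
    sigma2: np.ndarray

    def roi_mean_beta(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        return float(self.beta_map.values[mask].mean())

    def summary(self) -> pd.DataFrame:
        v = self.beta_map.values.ravel()
        t = self.t_map.values.ravel()
        return pd.DataFrame(
            {
                "statistic": ["beta", "t"],
                "mean": [v.mean(), t.mean()],
                "max": [v.max(), t.max()],
                "min": [v.min(), t.min()],
                "df": [self.df, self.df],
            }
        )


def fit_glm(bold: Bold4D, design: TaskDesign) -> tuple[StatMap, StatMap]:
    """Convenience wrapper: fit and return (beta map, t map)."""
    res = VoxelGLM(bold, design).fit()
    return res.beta_map, res.t_map


def percent_signal_change(bold: Bold4D, baseline_window: tuple[int, int]) -> Bold4D:
    """Express each voxel series relative to its pre-injection baseline.

    ``baseline_window`` is a half-open volume range (start, stop).
    Returns 100 * (value - baseline mean) / baseline mean per voxel.
    """
    lo, hi = baseline_window
    if not (0 <= lo < hi <= bold.n_volumes):
        raise ValueError("baseline window empty or outside the scan")
    base = bold.data[..., lo:hi].mean(axis=3)
    if np.any(np.abs(base) < 1e-12):
        raise ValueError("baseline mean is zero in some voxels")
    psc = 100.0 * (bold.data - base[..., None]) / base[..., None]
    return bold.copy_with(psc)


def smooth_gaussian(volume: np.ndarray, fwhm_mm, voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing with zero-padded boundaries.

    sigma per axis = FWHM / sqrt(8 ln 2) converted to voxel units.
    ``fwhm_mm`` may be a scalar or a 3-vector; 0 is the identity.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be non-negative")
    if np.all(fwhm == 0):
        return volume.copy()
    vox = np.asarray(voxel_size_mm, dtype=float)
    sigma_vox = fwhm / np.sqrt(8.0 * np.log(2.0)) / vox
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="constant", cval=0.0)


def _one_sample_t(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """t = mean / (sd / sqrt(n)) along axis 0 with degenerate handling."""
    n = values.shape[0]
    df = n - 1
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degen = sd <= _VAR_EPS * np.maximum(np.abs(mean), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degen, 0.0, mean / np.where(sd > 0, sd / np.sqrt(n), np.inf))
    p = np.where(degen, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p, degen, df


def group_one_sample_t(beta_maps: list[StatMap]) -> tuple[StatMap, StatMap]:
    """Group activation: voxelwise one-sample t across per-session betas."""
    if len(beta_maps) < 2:
        raise ValueError("need at least two beta maps")
    grid = beta_maps[0].grid_shape
    vs = beta_maps[0].voxel_size_mm
    for m in beta_maps[1:]:
        if m.grid_shape != grid:
            raise ValueError("beta maps must share a grid")
    stack = np.stack([m.values for m in beta_maps])
    t, p, degen, df = _one_sample_t(stack)
    return (
        StatMap(t, "t", df=df, voxel_size_mm=vs, degenerate=degen),
        StatMap(p, "p", df=df, voxel_size_mm=vs),
    )


def paired_t(maps_a: list[StatMap], maps_b: list[StatMap]) -> tuple[StatMap, StatMap]:
    """Paired comparison (drug vs saline): one-sample t on differences."""
    if len(maps_a) != len(maps_b):
        raise ValueError("paired t requires equal, matched subject counts")
    if len(maps_a) < 2:
        raise ValueError("need at least two pairs")
    diffs = [StatMap(a.values - b.values, "beta", voxel_size_mm=a.voxel_size_mm)
             for a, b in zip(maps_a, maps_b)]
    return group_one_sample_t(diffs)


def fdr_threshold(
    p_map: StatMap, q: float = 0.0005, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg rejection mask over in-mask voxels.

    Returns (3D boolean rejection mask, largest rejected p); the critical
    p is nan when nothing is rejected.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    vals = p_map.values
    if mask is None:
        mask = np.ones(vals.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    pv = vals[mask]
    if pv.size == 0:
        raise ValueError("empty p-value set")
    reject, *_ = multipletests(pv, alpha=q, method="fdr_bh")
    out = np.zeros(vals.shape, dtype=bool)
    out[mask] = reject
    crit = float(pv[reject].max()) if reject.any() else float("nan")
    return out, crit


def block_length_sweep(
    bold: Bold4D,
    candidate_lengths_s,
    target_mask: np.ndarray,
    onset_s: float,
    hrf_params: HrfParams | None = None,
    *,
    confounds: dict[str, np.ndarray] | None = None,
    score: str = "mean_t",
) -> tuple[float, pd.DataFrame]:
    """Choose the modelled response-epoch length maximising target activation.

    For each candidate block length the GLM is refitted and scored over
    the target mask (the inferior olive in the primary analysis).  Scores:
    ``mean_t`` (default), ``peak_t`` or ``count`` (suprathreshold voxels
    at |t| > 2).  Ties break toward the shortest candidate.
    """
    cands = [float(c) for c in candidate_lengths_s]
    if not cands:
        raise ValueError("no candidate block lengths")
    target_mask = np.asarray(target_mask, dtype=bool)
    if not target_mask.any():
        raise ValueError("empty target mask")
    if score not in ("mean_t", "peak_t", "count"):
        raise ValueError("score must be mean_t, peak_t or count")

    rows = []
    for L in cands:
        design = build_design(bold.n_volumes, bold.tr_s, onset_s, L,
                              hrf_params, confounds=confounds)
        res = VoxelGLM(bold, design).fit()
        tvals = res.t_map.values[target_mask]
        rows.append(
            {
                "block_length_s": L,
                "mean_t": float(tvals.mean()),
                "peak_t": float(tvals.max()),
                "count": int((np.abs(tvals) > 2.0).sum()),
            }
        )
    table = pd.DataFrame(rows).sort_values("block_length_s").reset_index(drop=True)
    best_score = table[score].max()
    best = float(table.loc[table[score] >= best_score, "block_length_s"].min())
    return best, table


PEAK_TABLE_COLUMNS = ["hemisphere", "area", "x", "y", "z", "cluster_size", "t"]


def _mm_coords(index: tuple[int, ...], shape, voxel_size_mm) -> np.ndarray:
    centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    return (np.asarray(index, dtype=float) - centre) * np.asarray(voxel_size_mm)


def cluster_peaks(
    t_map: StatMap,
    threshold: float,
    min_cluster: int = 1,
    atlas: AtlasVolume | None = None,
) -> pd.DataFrame:
    """Tabulate suprathreshold clusters of a t-map.

    26-connected components of voxels with t > ``threshold``; one row per
    cluster with hemisphere (from the sign of the peak x coordinate, L/R
    when the cluster spans the midline), area name at the peak voxel,
    peak mm coordinates (1 decimal), cluster size and peak t.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = t_map.values
    supra = vals > threshold
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n_comp = ndimage.label(supra, structure=structure)
    rows = []
    for comp in range(1, n_comp + 1):
        idx = np.nonzero(labels == comp)
        size = idx[0].size
        if size < min_cluster:
            continue
        peak_flat = np.argmax(vals[idx])
        peak_idx = tuple(ax[peak_flat] for ax in idx)
        mm = _mm_coords(peak_idx, vals.shape, t_map.voxel_size_mm)
        xs = (np.asarray(idx[0], float) - (vals.shape[0] - 1) / 2.0) * t_map.voxel_size_mm[0]
        has_l, has_r = bool((xs > 1e-9).any()), bool((xs < -1e-9).any())
        if has_l and has_r:
            hemi = "L/R"
        elif mm[0] > 1e-9:
            hemi = "L"
        elif mm[0] < -1e-9:
            hemi = "R"
        else:
            hemi = "L/R"
        area = "unknown"
        if atlas is not None:
            lab = int(atlas.labels[peak_idx])
            area = atlas.label_table.get(lab, "background") if lab else "background"
        rows.append(
            {
                "hemisphere": hemi,
                "area": area,
                "x": round(float(mm[0]), 1),
                "y": round(float(mm[1]), 1),
                "z": round(float(mm[2]), 1),
                "cluster_size": int(size),
                "t": float(vals[peak_idx]),
            }
        )
    table = pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)
    return table.sort_values("cluster_size", ascending=False).reset_index(drop=True) \
        if len(table) else table
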