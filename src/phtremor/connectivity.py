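"""ROI partial-correlation networks with permutation significance.

Functional coupling between named ROIs is quantified as the partial
correlation of ROI-mean BOLD series: the correlation of each pair
conditioned on all remaining ROIs, computed from the inverse sample
covariance (precision matrix).  A residualisation route (correlate the
OLS residuals of each member of the pair on all other ROIs) is provided
as an algebraically equivalent cross-check.  Scan epochs are split at
the injection (pre 0-232 s, post 234-484 s), each epoch demeaned
independently, and connectivity change is isolated by subtracting the
post-saline matrix from the post-drug matrix.  Significance per cell
comes from a permutation null: the time samples of one ROI are shuffled
(n = 2000 by default) while the rest stay fixed, with the add-one
p-value convention so p is never exactly zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AtlasVolume, Bold4D, RoiTimeSeries

__all__ = [
    "roi_mean_series",
    "partial_correlation",
    "partial_correlation_residual",
    "split_epochs",
    "connectivity_change",
    "ConnectivityChange",
    "permutation_test",
    "PartialCorrelationModel",
    "PartialCorrResults",
]


def roi_mean_series(
    bold: Bold4D, atlas: AtlasVolume, roi_names=None
) -> RoiTimeSeries:
    """Unweighted mean BOLD series per named ROI."""
    if atlas.grid_shape != bold.grid_shape:
        raise ValueError("atlas and BOLD grids differ")
    names = list(roi_names) if roi_names is not None else atlas.roi_names
    rows = []
    for nm in names:
        mask = atlas.roi_mask(nm)
        rows.append(bold.data[mask].mean(axis=0))
    return RoiTimeSeries(np.vstack(rows), names, bold.tr_s)


def _covariance(data: np.ndarray) -> np.ndarray:
    x = data - data.mean(axis=1, keepdims=True)
    return x @ x.T / (x.shape[1] - 1)


def partial_correlation(
    data_or_series, *, ridge: float | None = None
) -> np.ndarray:
    """Partial-correlation matrix from the precision matrix.

    rho_ij|rest = -P_ij / sqrt(P_ii P_jj) with P the inverse sample
    covariance of the (row-demeaned) ROI series.  A singular covariance
    triggers a documented ridge fallback (eps = 1e-8 * trace / n on the
    diagonal) with a warning; pass ``ridge`` to control it explicitly.
    """
    data = data_or_series.data if isinstance(data_or_series, RoiTimeSeries) else \
        np.asarray(data_or_series, dtype=float)
    r, t = data.shape
    if t <= r + 1:
        raise ValueError("need more time points than ROIs + 1")
    sds = data.std(axis=1)
    if np.any(sds <= 1e-12 * np.maximum(1.0, np.abs(data).max())):
        raise ValueError("constant ROI series")
    cov = _covariance(data)
    if ridge is not None:
        cov = cov + ridge * np.eye(r)
    try:
        prec = np.linalg.inv(cov)
        if not np.all(np.isfinite(prec)) or np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        import warnings

        eps = 1e-8 * np.trace(cov) / r
        warnings.warn(
            f"singular ROI covariance; applying ridge eps={eps:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
        prec = np.linalg.inv(cov + eps * np.eye(r))
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    pc = np.clip((pc + pc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pc, 1.0)
    return pc


def partial_correlation_residual(data_or_series) -> np.ndarray:
    """Residualisation route: corr of OLS residuals on the other ROIs.

    Algebraically identical to the precision formula; kept as an
    independent implementation path for validation.
    """
    data = data_or_series.data if isinstance(data_or_series, RoiTimeSeries) else \
        np.asarray(data_or_series, dtype=float)
    r, t = data.shape
    x = data - data.mean(axis=1, keepdims=True)
    pc = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            others = [k for k in range(r) if k not in (i, j)]
            if others:
                Z = np.column_stack([np.ones(t)] + [x[k] for k in others])
            else:
                Z = np.ones((t, 1))
            proj = Z @ np.linalg.pinv(Z)
            ri = x[i] - proj @ x[i]
            rj = x[j] - proj @ x[j]
            denom = np.linalg.norm(ri) * np.linalg.norm(rj)
            pc[i, j] = pc[j, i] = float(ri @ rj / denom) if denom > 0 else 0.0
    return pc


def split_epochs(
    series: RoiTimeSeries,
    pre_s: tuple[float, float] = (0.0, 232.0),
    post_s: tuple[float, float] = (234.0, 484.0),
) -> tuple[RoiTimeSeries, RoiTimeSeries]:
    """Split at the injection: volumes assigned by onset time.

    Pre takes onsets in [pre_lo, pre_hi] (closed), post takes onsets in
    [post_lo, post_hi) (half-open); the defaults give 117 and 125
    volumes at TR 2 s.  Epochs must be disjoint and non-empty.
    """
    onsets = series.frame_times()
    if pre_s[1] >= post_s[0] and post_s[1] > pre_s[0]:
        raise ValueError("epochs overlap")
    pre_sel = (onsets >= pre_s[0] - 1e-9) & (onsets <= pre_s[1] + 1e-9)
    post_sel = (onsets >= post_s[0] - 1e-9) & (onsets < post_s[1] - 1e-9)
    if not pre_sel.any() or not post_sel.any():
        raise ValueError("an epoch contains no volumes")
    if (pre_sel & post_sel).any():
        raise ValueError("epochs overlap")
    pre = RoiTimeSeries(series.data[:, pre_sel], series.roi_names, series.tr_s,
                        t0_s=float(onsets[pre_sel][0]))
    post = RoiTimeSeries(series.data[:, post_sel], series.roi_names, series.tr_s,
                         t0_s=float(onsets[post_sel][0]))
    return pre, post


@dataclass
class ConnectivityChange:
    """Connectivity-change matrices of one drug session.

    ``delta`` (primary) = PC(drug post) - PC(saline post); the pre/post
    differences within each condition are reported alongside because the
    analysis defines both contrasts.
    """

    delta: pd.DataFrame
    drug_post_minus_pre: pd.DataFrame
    saline_post_minus_pre: pd.DataFrame


def _as_frame(mat: np.ndarray, names) -> pd.DataFrame:
    return pd.DataFrame(mat, index=list(names), columns=list(names))


def connectivity_change(
    harm_pre: np.ndarray, harm_post: np.ndarray,
    sal_pre: np.ndarray, sal_post: np.ndarray,
    roi_names,
) -> ConnectivityChange:
    mats = [np.asarray(m, dtype=float) for m in (harm_pre, harm_post, sal_pre, sal_post)]
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise ValueError("matrices must share the ROI set")
    if shape[0] != len(list(roi_names)):
        raise ValueError("roi_names length must match matrix size")
    hp, hq, sp, sq = mats
    return ConnectivityChange(
        delta=_as_frame(hq - sq, roi_names),
        drug_post_minus_pre=_as_frame(hq - hp, roi_names),
        saline_post_minus_pre=_as_frame(sq - sp, roi_names),
    )


def permutation_test(
    series: RoiTimeSeries | np.ndarray,
    roi_a: int | str,
    roi_b: int | str,
    n_perm: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for one partial-correlation cell.

    The time samples of ``roi_a`` are shuffled ``n_perm`` times while all
    other ROIs stay in order; the null statistic is the partial
    correlation of the pair given the rest, recomputed per shuffle via
    the residualisation identity (the conditioning residual of the
    unshuffled ROIs is fixed, so only roi_a is re-residualised).
    p = (1 + #{|null| >= |observed|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(series, RoiTimeSeries):
        data = series.data
        ia = series.index_of(roi_a) if isinstance(roi_a, str) else int(roi_a)
        ib = series.index_of(roi_b) if isinstance(roi_b, str) else int(roi_b)
    else:
        data = np.asarray(series, dtype=float)
        ia, ib = int(roi_a), int(roi_b)
    if ia == ib:
        raise ValueError("roi_a and roi_b must differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    r, t = data.shape
    x = data - data.mean(axis=1, keepdims=True)
    others = [k for k in range(r) if k not in (ia, ib)]
    Z = np.column_stack([np.ones(t)] + [x[k] for k in others])
    proj = Z @ np.linalg.pinv(Z)
    resid_b = x[ib] - proj @ x[ib]
    nb = np.linalg.norm(resid_b)
    if nb <= 0:
        raise ValueError("conditioned series of roi_b is constant")

    def _pc(a_vec: np.ndarray) -> float:
        ra = a_vec - proj @ a_vec
        na = np.linalg.norm(ra)
        return float(ra @ resid_b / (na * nb)) if na > 0 else 0.0

    observed = _pc(x[ia])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(t)
        if abs(_pc(x[ia][perm])) >= abs(observed) - 1e-15:
            count += 1
    return (1 + count) / (n_perm + 1)


class PartialCorrelationModel:
    """ROI-network model: partial correlations with optional permutation p.

    Built from a :class:`RoiTimeSeries`; ``fit(n_perm=..., seed=...)``
    returns a :class:`PartialCorrResults` whose ``p_values`` frame is
    populated when permutations are requested.
    """

    def __init__(self, series: RoiTimeSeries, *, ridge: float | None = None):
        self.series = series
        self.ridge = ridge

    def fit(self, n_perm: int | None = None,
            seed: int | None = None) -> "PartialCorrResults":
        values = partial_correlation(self.series, ridge=self.ridge)
        names = list(self.series.roi_names)
        pvals = None
        if n_perm:
            ss = np.random.SeedSequence(seed)
            pvals = np.full(values.shape, np.nan)
            r = len(names)
            children = ss.spawn(r * (r - 1) // 2)
            ci = 0
            for i in range(r):
                for j in range(i + 1, r):
                    rng = np.random.default_rng(children[ci])
                    ci += 1
                    p = permutation_test(self.series, i, j, n_perm=n_perm, seed=rng)
                    pvals[i, j] = pvals[j, i] = p
        return PartialCorrResults(
            values=_as_frame(values, names),
            p_values=_as_frame(pvals, names) if pvals is not None else None,
            n_perm=n_perm or 0,
            seed=seed,
        )


@dataclass
class PartialCorrResults:
    values: pd.DataFrame
    p_values: pd.DataFrame | None
    n_perm: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def roi_names(self) -> list[str]:
        return list(self.values.index)

    def significant(self, alpha: float = 0.001) -> pd.DataFrame:
        """Boolean mask of significant off-diagonal cells (Fig-style dots)."""
        if self.p_values is None:
            raise ValueError("fit with n_perm to obtain p-values")
        sig = self.p_values < alpha
        np.fill_diagonal(sig.values, False)
        return sig

    def summary(self) -> pd.DataFrame:
        rows = []
        names = self.roi_names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                row = {
                    "roi_a": names[i],
                    "roi_b": names[j],
                    "partial_r": float(self.values.iloc[i, j]),
                }
                if self.p_values is not None:
                    row["p_perm"] = float(self.p_values.iloc[i, j])
                rows.append(row)
        return pd.DataFrame(rows)
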