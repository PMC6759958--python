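"""End-to-end orchestration: simulate -> physio -> activate -> tremor ->
connect -> link -> report.

``run_pipeline`` drives the full analysis on a simulated experiment and
writes every figure-analog table (activation peak tables, tremor trend
tables, connectivity-change matrices, beta-tremor link table) plus a run
manifest tying each output to the configuration and seed.  Stages are
individually skippable; all randomness derives from the configured seed.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .activation import (
    VoxelGLM,
    block_length_sweep,
    cluster_peaks,
    fdr_threshold,
    group_one_sample_t,
    paired_t,
    percent_signal_change,
    smooth_gaussian,
)
from .config import NETWORK_ROIS, ExperimentConfig, SessionTruth
from .connectivity import (
    PartialCorrelationModel,
    connectivity_change,
    partial_correlation,
    roi_mean_series,
    split_epochs,
)
from .design import build_design
from .link import BetaTremorRegression
from .physio import (
    DegenerateRegressorError,
    NuisanceRegression,
    build_nuisance_design,
    resample_to_volumes,
)
from .synthio import Experiment, simulate_experiment
from .tremor import TremorAnalysis, session_trend_stats
from .types import StatMap

__all__ = ["run_pipeline", "RunManifest", "analyze_fmri_session", "PipelineError"]

logger = logging.getLogger("phtremor")

ALL_STAGES = ("simulate", "physio", "activate", "tremor", "connect", "link", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Traceability record of one pipeline run."""

    config: dict
    seed: int
    software_version: str
    stages_run: list[str]
    outputs: dict[str, str] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    timestamp: float = 0.0

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "software_version": self.software_version,
            "stages_run": self.stages_run,
            "outputs": self.outputs,
            "parameters": self.parameters,
            "timestamp": self.timestamp,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def analyze_fmri_session(
    bold,
    hr_times,
    hr_values,
    *,
    onset_s: float,
    block_length_s: float = 25.0,
    baseline_window: tuple[int, int] | None = None,
    include_hr_confound: bool = True,
    smooth_fwhm_mm: float | None = None,
):
    """Single-session analysis: nuisance correction, PSC conversion, GLM.

    Returns the :class:`~phtremor.activation.VoxelGLMResults` of the
    percent-signal-change fit (betas are in % units).  The heart-rate
    regressor is reused as a confound column of the activation design so
    the task estimate matches the joint model.  ``smooth_fwhm_mm``
    applies Gaussian spatial smoothing to each frame before the fit
    (off by default; the full pipeline uses the conventional 2.8 mm).
    """
    n_vol = bold.n_volumes
    if smooth_fwhm_mm:
        smoothed = np.empty_like(bold.data)
        for k in range(n_vol):
            smoothed[..., k] = smooth_gaussian(
                bold.data[..., k], smooth_fwhm_mm, bold.voxel_size_mm)
        bold = bold.copy_with(smoothed)
    try:
        hr_reg = resample_to_volumes(hr_times, hr_values, n_vol, bold.tr_s)
        have_hr = True
    except DegenerateRegressorError:
        # flat heart rate (e.g. saline): nothing to regress out
        hr_reg = None
        have_hr = False
    if have_hr:
        ndesign = build_nuisance_design(hr_reg)
        corrected = NuisanceRegression(bold, ndesign).fit().residual
    else:
        corrected = bold
    if baseline_window is None:
        baseline_window = (0, int(onset_s // bold.tr_s))
    psc = percent_signal_change(corrected, baseline_window)
    confounds = {"heart_rate": hr_reg} if (have_hr and include_hr_confound) else None
    design = build_design(n_vol, bold.tr_s, onset_s, block_length_s,
                          confounds=confounds)
    return VoxelGLM(psc, design).fit()


def _group_epoch_series(series_list):
    """Concatenate per-animal epoch series after per-animal demeaning."""
    demeaned = [s.data - s.data.mean(axis=1, keepdims=True) for s in series_list]
    return np.concatenate(demeaned, axis=1)


def run_pipeline(
    config: ExperimentConfig,
    out_dir,
    *,
    base_truth: SessionTruth | None = None,
    stages=None,
    block_length_s: float = 25.0,
    sweep_candidates=None,
    q_fdr: float = 0.0005,
    p_paired: float = 0.005,
    p_link: float = 0.05,
    n_perm: int = 2000,
    min_cluster: int = 5,
    smooth_fwhm_mm: float | None = 2.8,
) -> RunManifest:
    """Run the full pipeline on a simulated experiment; write all tables."""
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError("config", f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        software_version=_version(),
        stages_run=stages,
        parameters={
            "block_length_s": block_length_s,
            "q_fdr": q_fdr,
            "p_paired": p_paired,
            "p_link": p_link,
            "n_perm": n_perm,
            "min_cluster": min_cluster,
            "smooth_fwhm_mm": smooth_fwhm_mm,
        },
        timestamp=time.time(),
    )

    # ---- simulate -------------------------------------------------------
    if "simulate" not in stages:
        raise PipelineError("simulate",
                            "this pipeline entry point requires the simulate stage")
    logger.info("simulate: %d animals, %d sessions each",
                config.n_animals, len(config.session_schedule))
    exp = simulate_experiment(config, base_truth=base_truth)
    atlas = exp.atlas
    pio.write_volume(atlas, out / "atlas.nii.gz")
    pio.write_truth_ledger(exp.truth_ledger, out / "truth_ledger.yaml")
    manifest.outputs["atlas"] = "atlas.nii.gz"
    manifest.outputs["truth_ledger"] = "truth_ledger.yaml"

    # ---- physio + per-session GLM --------------------------------------
    session_results: dict[str, dict[int, object]] = {}
    if "physio" in stages or "activate" in stages:
        for animal, sess in exp.sessions():
            if sess.bold is None:
                continue
            logger.info("physio+glm: %s session %d (%s)", animal,
                        sess.session_index, sess.kind)
            res = analyze_fmri_session(
                sess.bold, sess.hr_trace[0], sess.hr_trace[1],
                onset_s=config.injection_onset_s,
                block_length_s=block_length_s,
                smooth_fwhm_mm=smooth_fwhm_mm,
            )
            session_results.setdefault(animal, {})[sess.session_index] = (sess, res)

    harm_indices = sorted(
        {s.session_index for _, s in exp.sessions("fmri_harmaline")}
    )
    saline_indices = sorted(
        {s.session_index for _, s in exp.sessions("fmri_saline")}
    )

    # ---- activate -------------------------------------------------------
    if "activate" in stages:
        if not session_results:
            raise PipelineError("activate", "no fMRI sessions available")
        harm_betas = [
            session_results[a][i][1].beta_map
            for a in session_results for i in harm_indices
        ]
        t_map, p_map = group_one_sample_t(harm_betas)
        mask, crit_p = fdr_threshold(p_map, q=q_fdr, mask=atlas.brain_mask())
        if mask.any():
            thr_t = float(np.min(t_map.values[mask & (t_map.values > 0)]) - 1e-9) \
                if (mask & (t_map.values > 0)).any() else float("inf")
        else:
            thr_t = float("inf")
        peaks = cluster_peaks(
            StatMap(np.where(mask, t_map.values, 0.0), "t", df=t_map.df,
                    voxel_size_mm=t_map.voxel_size_mm),
            threshold=0.0, min_cluster=min_cluster, atlas=atlas,
        )
        peaks.to_csv(out / "group_activation_peaks.tsv", sep="\t", index=False)
        manifest.outputs["group_activation_peaks"] = "group_activation_peaks.tsv"
        manifest.parameters["fdr_critical_p"] = crit_p

        if sweep_candidates is not None:
            a0 = sorted(session_results)[0]
            sess0, res0 = session_results[a0][harm_indices[0]]
            hr_reg = None
            try:
                hr_reg = resample_to_volumes(
                    sess0.hr_trace[0], sess0.hr_trace[1],
                    sess0.bold.n_volumes, sess0.bold.tr_s)
            except DegenerateRegressorError:
                pass
            ndesign = build_nuisance_design(hr_reg) if hr_reg is not None else None
            corrected = NuisanceRegression(sess0.bold, ndesign).fit().residual \
                if ndesign is not None else sess0.bold
            psc = percent_signal_change(
                corrected, (0, int(config.injection_onset_s // config.tr_s)))
            best, sweep_table = block_length_sweep(
                psc, sweep_candidates, atlas.roi_mask("ION"),
                config.injection_onset_s,
                confounds={"heart_rate": hr_reg} if hr_reg is not None else None,
            )
            sweep_table.to_csv(out / "block_length_sweep.tsv", sep="\t", index=False)
            manifest.outputs["block_length_sweep"] = "block_length_sweep.tsv"
            manifest.parameters["sweep_selected_block_s"] = best

        # per-session paired t vs saline
        if saline_indices:
            sal_i = saline_indices[0]
            for k, h_i in enumerate(harm_indices, start=1):
                maps_h = [session_results[a][h_i][1].beta_map
                          for a in sorted(session_results)]
                maps_s = [session_results[a][sal_i][1].beta_map
                          for a in sorted(session_results)]
                t_k, p_k = paired_t(maps_h, maps_s)
                supra = (p_k.values < p_paired) & (t_k.values > 0)
                pk = cluster_peaks(
                    StatMap(np.where(supra, t_k.values, 0.0), "t", df=t_k.df,
                            voxel_size_mm=t_k.voxel_size_mm),
                    threshold=0.0, min_cluster=min_cluster, atlas=atlas,
                )
                fname = f"session{k}_paired_peaks.tsv"
                pk.to_csv(out / fname, sep="\t", index=False)
                manifest.outputs[f"session{k}_paired_peaks"] = fname

    # ---- tremor ---------------------------------------------------------
    tremor_max: dict[str, dict[int, float]] = {}
    tremor_dur: dict[str, dict[int, float]] = {}
    if "tremor" in stages:
        for animal, sess in exp.sessions("behavior"):
            logger.info("tremor: %s session %d", animal, sess.session_index)
            res = TremorAnalysis(sess.accel).fit()
            tremor_max.setdefault(animal, {})[sess.session_index] = res.max_index
            tremor_dur.setdefault(animal, {})[sess.session_index] = res.duration_s
        if tremor_max:
            max_df = pd.DataFrame(tremor_max).T.sort_index()
            dur_df = pd.DataFrame(tremor_dur).T.sort_index()
            max_df.columns = [f"behavior_{i + 1}" for i in range(max_df.shape[1])]
            dur_df.columns = list(max_df.columns)
            max_df.to_csv(out / "tremor_max_index.tsv", sep="\t")
            dur_df.to_csv(out / "tremor_duration_s.tsv", sep="\t")
            manifest.outputs["tremor_max_index"] = "tremor_max_index.tsv"
            manifest.outputs["tremor_duration_s"] = "tremor_duration_s.tsv"
            if max_df.shape[0] >= 2 and max_df.shape[1] >= 2:
                trend = session_trend_stats(max_df, dur_df)
                trend["pairwise_paired_t"].to_csv(
                    out / "tremor_trend_pairwise.tsv", sep="\t", index=False)
                manifest.outputs["tremor_trend_pairwise"] = "tremor_trend_pairwise.tsv"
                manifest.parameters["tremor_duration_anova_f"] = trend["anova_f"]
                manifest.parameters["tremor_duration_anova_p"] = trend["anova_p"]

    # ---- connect --------------------------------------------------------
    if "connect" in stages:
        if not session_results:
            raise PipelineError("connect", "no fMRI sessions available")
        if not saline_indices:
            raise PipelineError("connect", "no saline session for subtraction")
        sal_i = saline_indices[0]
        roi_names = list(NETWORK_ROIS)
        pre_bounds = (0.0, config.injection_onset_s - config.tr_s)
        post_bounds = (config.injection_onset_s, config.scan_duration_s)

        def _epochs(animal, s_index):
            sess, res = session_results[animal][s_index]
            series = roi_mean_series(sess.bold, atlas, roi_names)
            return split_epochs(series, pre_bounds, post_bounds)

        perm_root = np.random.SeedSequence(config.seed).spawn(1)[0]
        for k, h_i in enumerate(harm_indices, start=1):
            logger.info("connect: harmaline session %d", k)
            animals = sorted(session_results)
            hp = [_epochs(a, h_i)[0] for a in animals]
            hq = [_epochs(a, h_i)[1] for a in animals]
            sp = [_epochs(a, sal_i)[0] for a in animals]
            sq = [_epochs(a, sal_i)[1] for a in animals]
            pc = {
                nm: partial_correlation(_group_epoch_series(lst))
                for nm, lst in (("hp", hp), ("hq", hq), ("sp", sp), ("sq", sq))
            }
            change = connectivity_change(pc["hp"], pc["hq"], pc["sp"], pc["sq"],
                                         roi_names)
            pio.write_matrix(change.delta, out / f"session{k}_delta.tsv")
            manifest.outputs[f"session{k}_delta"] = f"session{k}_delta.tsv"
            if n_perm:
                from .types import RoiTimeSeries

                group_post = RoiTimeSeries(
                    _group_epoch_series(hq), roi_names, config.tr_s)
                model = PartialCorrelationModel(group_post)
                seed_k = int(perm_root.generate_state(1)[0] % (2**31)) + k
                pcr = model.fit(n_perm=n_perm, seed=seed_k)
                pio.write_matrix(pcr.p_values, out / f"session{k}_perm_p.tsv")
                manifest.outputs[f"session{k}_perm_p"] = f"session{k}_perm_p.tsv"

    # ---- link -----------------------------------------------------------
    if "link" in stages:
        if not session_results or not tremor_max:
            raise PipelineError(
                "link", "requires both fMRI session results and tremor metrics")
        behavior_indices = sorted(
            {s.session_index for _, s in exp.sessions("behavior")})
        n_pairs = min(len(harm_indices), len(behavior_indices))
        maps, indices = [], []
        for a in sorted(session_results):
            for k in range(n_pairs):
                maps.append(session_results[a][harm_indices[k]][1].beta_map)
                indices.append(tremor_max[a][behavior_indices[k]])
        res = BetaTremorRegression(maps, indices).fit()
        supra = res.suprathreshold_mask(p_link) & (res.slope_map.values > 0)
        link_peaks = cluster_peaks(
            StatMap(np.where(supra, res.t_map.values, 0.0), "t", df=res.df,
                    voxel_size_mm=res.t_map.voxel_size_mm),
            threshold=0.0, min_cluster=min_cluster, atlas=atlas,
        )
        link_peaks.to_csv(out / "beta_tremor_peaks.tsv", sep="\t", index=False)
        manifest.outputs["beta_tremor_peaks"] = "beta_tremor_peaks.tsv"
        manifest.parameters["beta_tremor_n_obs"] = res.n_obs

    # ---- report ---------------------------------------------------------
    if "report" in stages:
        manifest.save(out / "manifest.json")
        manifest.outputs["manifest"] = "manifest.json"
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("phtremor")
    except Exception:
        return "unknown"
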