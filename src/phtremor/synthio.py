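"""Synthetic experiment generator with known ground truth.

No in vivo data accompany the study design this package implements, so
every analysis is exercised on simulated sessions whose generative
parameters are recorded in a machine-readable truth ledger:

* BOLD sessions: per-voxel baseline level plus an ROI-localised drug
  response (amplitude in percent signal change times the HRF-convolved
  injection block), a bradycardia-coupled global drift (per-tissue gain
  times the relative heart-rate deviation resampled to volume times),
  ROI-level shared fluctuations that create the post-injection
  cerebello-thalamic / cerebello-DCN coupling, and white Gaussian voxel
  noise.  Temporal autocorrelation is deliberately omitted.
* Heart rate: constant baseline, then a smooth drop to a nadir with
  exponential recovery after the injection onset.
* Accelerometer: broadband sub-10-Hz motion plus, after injection, a
  tremor oscillation (default 13 Hz) with a rising/decaying envelope.
* Tolerance: response amplitudes, tremor amplitude and network coupling
  all shrink by decay^(injections so far).

All randomness flows from one root seed through a hierarchical
``numpy.random.SeedSequence`` (experiment -> animal -> session ->
stream), so identical (config, seed) pairs give bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import ALL_ROIS, ExperimentConfig, SessionDescriptor, SessionTruth
from .design import build_design
from .types import AccelTrace, AtlasVolume, Bold4D, SessionEvents

__all__ = [
    "make_atlas",
    "default_atlas",
    "simulate_heart_rate",
    "simulate_bold_session",
    "simulate_accelerometer",
    "simulate_experiment",
    "Experiment",
    "SimulatedSession",
    "DEFAULT_ROI_BLOCKS",
]

DEFAULT_GRID = (24, 24, 16)

#: labelled cuboid stand-ins for the seven analysis regions on the
#: default 24 x 24 x 16 grid: (x0, x1, y0, y1, z0, z1) half-open
DEFAULT_ROI_BLOCKS: dict[str, tuple[int, int, int, int, int, int]] = {
    "SMC": (4, 10, 2, 8, 10, 14),
    "thalamus": (9, 15, 9, 14, 7, 11),
    "limbic": (15, 20, 3, 8, 8, 12),
    "cerebellum": (8, 16, 16, 22, 4, 9),
    "DCN": (10, 14, 14, 16, 3, 6),
    "visual": (16, 21, 9, 14, 11, 15),
    "ION": (10, 14, 17, 20, 0, 3),
}


def make_atlas(
    grid_shape: tuple[int, int, int],
    roi_spec: list[tuple[str, tuple[int, int, int, int, int, int]]],
    voxel_size_mm=(1.7, 1.7, 2.4),
) -> AtlasVolume:
    """Build a label volume from named, disjoint voxel blocks.

    ``roi_spec`` is an ordered list of (name, (x0, x1, y0, y1, z0, z1))
    with half-open bounds; labels are assigned 1..n in order.
    """
    if not roi_spec:
        raise ValueError("empty ROI specification")
    labels = np.zeros(grid_shape, dtype=np.int32)
    table: dict[int, str] = {}
    for lab, (name, (x0, x1, y0, y1, z0, z1)) in enumerate(roi_spec, start=1):
        if not (0 <= x0 < x1 <= grid_shape[0]
                and 0 <= y0 < y1 <= grid_shape[1]
                and 0 <= z0 < z1 <= grid_shape[2]):
            raise ValueError(f"ROI {name!r} block outside the grid")
        block = labels[x0:x1, y0:y1, z0:z1]
        if np.any(block != 0):
            raise ValueError(f"ROI {name!r} overlaps a previous block")
        labels[x0:x1, y0:y1, z0:z1] = lab
        table[lab] = name
    return AtlasVolume(labels=labels, voxel_size_mm=voxel_size_mm, label_table=table)


def default_atlas(grid_shape=DEFAULT_GRID, voxel_size_mm=(1.7, 1.7, 2.4)) -> AtlasVolume:
    """The seven-ROI default atlas (six network ROIs plus the ION)."""
    spec = [(name, DEFAULT_ROI_BLOCKS[name]) for name in ALL_ROIS]
    return make_atlas(grid_shape, spec, voxel_size_mm)


def simulate_heart_rate(
    config: ExperimentConfig,
    truth: SessionTruth,
    *,
    duration_s: float | None = None,
    sample_rate_hz: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Heart-rate trace (times s, bpm) over the scan.

    Baseline before the injection onset; afterwards the rate follows
    baseline - drop * g(t') / g(t_nadir) with
    g(t') = (1 - e^(-t'/tau_rise)) * e^(-max(0, t'-t_nadir)/tau_rec),
    normalised so the configured drop amplitude is attained exactly at
    the nadir.  Deterministic (the trace is noise-free by default).
    """
    if truth.hr_drop_bpm < 0:
        raise ValueError("drop amplitude must be non-negative")
    if truth.hr_baseline_bpm - truth.hr_drop_bpm <= 0:
        raise ValueError("drop would drive the heart rate to zero or below")
    duration = duration_s if duration_s is not None else config.scan_duration_s
    times = np.arange(0.0, duration + 1e-9, 1.0 / sample_rate_hz)
    tprime = times - config.injection_onset_s
    g = np.where(
        tprime > 0,
        (1.0 - np.exp(-np.maximum(tprime, 0.0) / truth.hr_rise_tau_s))
        * np.exp(-np.maximum(tprime - truth.hr_nadir_s, 0.0) / truth.hr_recovery_tau_s),
        0.0,
    )
    g_nadir = (1.0 - np.exp(-truth.hr_nadir_s / truth.hr_rise_tau_s))
    bpm = truth.hr_baseline_bpm - truth.hr_drop_bpm * g / g_nadir
    return times, bpm


def _roi_indices(atlas: AtlasVolume) -> dict[str, np.ndarray]:
    flat = atlas.labels.reshape(-1)
    return {
        name: np.nonzero(flat == lab)[0]
        for lab, name in atlas.label_table.items()
    }


def simulate_bold_session(
    atlas: AtlasVolume,
    config: ExperimentConfig,
    truth: SessionTruth,
    condition: str = "harmaline",
    rng: np.random.Generator | None = None,
    tissue_labels: np.ndarray | None = None,
) -> tuple[Bold4D, tuple[np.ndarray, np.ndarray]]:
    """One fMRI session on the atlas grid; returns (Bold4D, HR trace).

    ``condition='saline'`` forces activation amplitudes, heart-rate drop
    and network coupling to zero.  ``tissue_labels`` maps voxels to
    {1: gray, 2: white, 3: csf}; by default every voxel is gray.
    """
    if condition not in ("harmaline", "saline"):
        raise ValueError("condition must be 'harmaline' or 'saline'")
    if condition == "saline":
        truth = truth.as_saline()
    rng = rng if rng is not None else np.random.default_rng(truth.seed)

    n_vol = config.n_volumes
    grid = atlas.grid_shape
    n_vox = int(np.prod(grid))
    base = truth.baseline_level

    # drug response regressor (truth block length, peak-normalised)
    task = build_design(
        n_vol, config.tr_s, config.injection_onset_s, truth.response_block_s
    ).regressor

    # heart-rate-coupled drift, resampled to volume onsets
    hr_times, hr_bpm = simulate_heart_rate(config, truth)
    onsets = np.arange(n_vol) * config.tr_s
    hr_at_vols = np.interp(onsets, hr_times, hr_bpm)
    rel_dev = (hr_at_vols - truth.hr_baseline_bpm) / truth.hr_baseline_bpm

    if tissue_labels is None:
        tissue = np.ones(n_vox, dtype=np.int8)
    else:
        tissue = np.asarray(tissue_labels).reshape(-1)
        if tissue.size != n_vox:
            raise ValueError("tissue volume does not match the atlas grid")
    gain_by_class = {1: truth.artifact_gain_pct.get("gray", 0.0),
                     2: truth.artifact_gain_pct.get("white", 0.0),
                     3: truth.artifact_gain_pct.get("csf", 0.0)}
    gains = np.zeros(n_vox)
    for cls, g in gain_by_class.items():
        gains[tissue == cls] = g

    data = np.empty((n_vox, n_vol))
    data[:] = base
    data += np.outer(gains, rel_dev) * (base / 100.0)

    roi_idx = _roi_indices(atlas)
    for name, idx in roi_idx.items():
        amp = truth.roi_amplitude_pct.get(name, 0.0)
        if amp:
            data[idx] += amp * (base / 100.0) * task

    # ROI-level fluctuations: idiosyncratic everywhere, plus shared
    # post-injection coupling signals between named pairs
    post = onsets >= config.injection_onset_s
    for name, idx in roi_idx.items():
        fluct = rng.standard_normal(n_vol) * truth.roi_fluct_pct * (base / 100.0)
        data[idx] += fluct
    for (a, b, strength) in truth.coupling:
        shared = rng.standard_normal(int(post.sum())) * strength * (base / 100.0)
        for name in (a, b):
            if name not in roi_idx:
                raise ValueError(f"coupling ROI {name!r} not in atlas")
            data[np.ix_(roi_idx[name], np.nonzero(post)[0])] += shared

    data += rng.standard_normal((n_vox, n_vol)) * truth.noise_pct * (base / 100.0)

    bold = Bold4D(data.reshape(grid + (n_vol,)), tr_s=config.tr_s,
                  voxel_size_mm=atlas.voxel_size_mm)
    return bold, (hr_times, hr_bpm)


def _lowpass_noise(n: int, rate_hz: float, cutoff_hz: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance broadband noise band-limited below ``cutoff_hz``."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    out = sps.sosfiltfilt(sos, white)
    sd = out.std()
    return out / sd if sd > 0 else out


def simulate_accelerometer(
    config: ExperimentConfig,
    truth: SessionTruth,
    session_index: int = 0,
    rng: np.random.Generator | None = None,
    *,
    injection_number: int | None = None,
) -> AccelTrace:
    """One behavioural accelerometer session.

    Baseline: broadband < 10 Hz motion plus a small white sensor-noise
    floor.  After the injection a tremor sinusoid at the configured
    frequency is added, its envelope rising over ~60 s, persisting and
    slowly decaying; the amplitude carries the tolerance decay for the
    given injection number (pass ``injection_number`` or rely on the
    session schedule via ``session_index``).
    """
    if truth.tremor_frequency_hz >= config.accel_rate_hz / 2.0:
        raise ValueError("tremor frequency must be below Nyquist")
    sched = config.session_schedule
    if not (0 <= session_index < len(sched)):
        raise ValueError("session_index outside the schedule")
    if injection_number is None:
        injection_number = sched[session_index].injection_number or 1
    decay = truth.tolerance_decay ** (injection_number - 1)
    rng = rng if rng is not None else np.random.default_rng(truth.seed)

    rate = config.accel_rate_hz
    n_base = int(round(config.behavior_baseline_s * rate))
    n_post = int(round(config.behavior_post_s * rate))
    n = n_base + n_post
    t = np.arange(n) / rate

    x = truth.motion_sd * _lowpass_noise(n, rate, 9.5, rng)
    x = x + truth.sensor_noise_sd * rng.standard_normal(n)

    amp = truth.tremor_amplitude * decay
    if amp > 0:
        tp = t - config.behavior_baseline_s
        rise_tau, decay_tau = 60.0, 2400.0
        envelope = np.where(
            tp > 0,
            (1.0 - np.exp(-np.maximum(tp, 0.0) / rise_tau))
            * np.exp(-np.maximum(tp, 0.0) / decay_tau),
            0.0,
        )
        phase = rng.uniform(0, 2 * np.pi)
        x = x + amp * envelope * np.sin(2 * np.pi * truth.tremor_frequency_hz * t + phase)

    events = SessionEvents(
        baseline_start_s=0.0,
        injection_s=config.behavior_baseline_s,
        end_s=n / rate,
    )
    return AccelTrace(samples=x, rate_hz=rate, t0_s=0.0, events=events)


@dataclass
class SimulatedSession:
    """One generated session plus its ground truth."""

    kind: str
    session_index: int
    injection_number: int
    truth: SessionTruth
    bold: Bold4D | None = None
    hr_trace: tuple[np.ndarray, np.ndarray] | None = None
    accel: AccelTrace | None = None


@dataclass
class Experiment:
    """A full simulated multi-animal experiment."""

    config: ExperimentConfig
    atlas: AtlasVolume
    animals: dict[str, list[SimulatedSession]]
    truth_ledger: dict = field(default_factory=dict)

    def sessions(self, kind: str | None = None):
        for animal, sess in self.animals.items():
            for s in sess:
                if kind is None or s.kind == kind:
                    yield animal, s


def simulate_experiment(
    config: ExperimentConfig,
    base_truth: SessionTruth | None = None,
    atlas: AtlasVolume | None = None,
    *,
    animal_variability: float = 0.15,
) -> Experiment:
    """Generate the full dataset: per animal, the scheduled fMRI and
    behavioural sessions with tolerance decay and a truth ledger.

    Per-animal severity (a lognormal factor with the given log-sd)
    multiplies both the activation amplitudes and the tremor amplitude,
    so animals that tremble more also activate more - the coupling the
    beta-vs-tremor regression is designed to detect.
    """
    if config.n_animals < 1:
        raise ValueError("need at least one animal")
    base_truth = base_truth or SessionTruth()
    atlas = atlas or default_atlas()

    root = np.random.SeedSequence(config.seed)
    animal_seqs = root.spawn(config.n_animals)
    animals: dict[str, list[SimulatedSession]] = {}
    ledger: dict = {"config_seed": config.seed, "animals": {}}

    for a_i, a_seq in enumerate(animal_seqs):
        animal_id = f"animal{a_i + 1:02d}"
        sess_seqs = a_seq.spawn(len(config.session_schedule) + 1)
        sev_rng = np.random.default_rng(sess_seqs[-1])
        severity = float(np.exp(sev_rng.normal(0.0, animal_variability)))

        sessions: list[SimulatedSession] = []
        ledger_sessions = []
        for s_i, desc in enumerate(config.session_schedule):
            rng = np.random.default_rng(sess_seqs[s_i])
            inj = desc.injection_number or 1
            truth = base_truth.decayed(inj)
            truth.roi_amplitude_pct = {
                k: v * severity for k, v in truth.roi_amplitude_pct.items()
            }
            truth.tremor_amplitude *= severity

            sess = SimulatedSession(
                kind=desc.kind, session_index=s_i,
                injection_number=inj, truth=truth,
            )
            if desc.kind in ("fmri_harmaline", "fmri_saline"):
                condition = "saline" if desc.kind == "fmri_saline" else "harmaline"
                bold, hr = simulate_bold_session(
                    atlas, config, truth, condition=condition, rng=rng
                )
                sess.bold = bold
                sess.hr_trace = hr
                if condition == "saline":
                    sess.truth = truth.as_saline()
            else:
                sess.accel = simulate_accelerometer(
                    config, truth, session_index=s_i, rng=rng,
                    injection_number=inj,
                )
            sessions.append(sess)
            ledger_sessions.append(
                {
                    "session_index": s_i,
                    "kind": desc.kind,
                    "injection_number": inj,
                    "severity": severity,
                    "truth": sess.truth.to_dict(),
                }
            )
        animals[animal_id] = sessions
        ledger["animals"][animal_id] = {
            "severity": severity,
            "sessions": ledger_sessions,
        }

    return Experiment(config=config, atlas=atlas, animals=animals,
                      truth_ledger=ledger)
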