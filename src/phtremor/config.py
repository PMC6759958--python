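"""Experiment configuration and ground-truth records for the simulator.

The defaults encode the study design this package analyses: 484-s scans of
242 volumes at TR 2 s with an intravenous injection initiated at t = 234 s
over 40 s; seven sessions per animal (three drug fMRI scans interleaved
with three behavioural accelerometer sessions, plus a saline-control scan
run immediately after the final drug scan), 72 h apart; behavioural
sessions with a 30-min baseline and up to 2 h of post-injection monitoring
sampled at 100 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

SESSION_KINDS = ("fmri_harmaline", "fmri_saline", "behavior")

#: six network ROIs used for connectivity, plus the inferior olive for
#: activation analyses
NETWORK_ROIS = ("SMC", "thalamus", "limbic", "cerebellum", "DCN", "visual")
ALL_ROIS = NETWORK_ROIS + ("ION",)


@dataclass
class SessionDescriptor:
    """One entry of the experimental schedule."""

    kind: str
    interval_h: float = 72.0
    #: 1-based count of drug injections delivered up to and including this
    #: session; saline sessions carry the count without incrementing it.
    injection_number: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SESSION_KINDS:
            raise ValueError(f"session kind must be one of {SESSION_KINDS}")


def default_schedule() -> list[SessionDescriptor]:
    """Alternating drug-fMRI / behaviour sessions, saline scan last.

    Injections 1, 3, 5 are the fMRI scans; 2, 4, 6 the behavioural
    sessions; the saline control follows the final drug scan within the
    same day (interval 0 h).
    """
    sched = []
    inj = 0
    for k in range(3):
        inj += 1
        sched.append(SessionDescriptor("fmri_harmaline", 72.0, inj))
        inj += 1
        sched.append(SessionDescriptor("behavior", 72.0, inj))
    sched.append(SessionDescriptor("fmri_saline", 0.0, inj))
    return sched


@dataclass
class ExperimentConfig:
    """Design parameters of a simulated experiment."""

    n_animals: int = 5
    n_volumes: int = 242
    tr_s: float = 2.0
    injection_onset_s: float = 234.0
    injection_duration_s: float = 40.0
    session_schedule: list[SessionDescriptor] = field(default_factory=default_schedule)
    accel_rate_hz: float = 100.0
    behavior_baseline_s: float = 1800.0
    behavior_post_s: float = 7200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.n_volumes < 1:
            raise ValueError("counts must be >= 1")
        if self.tr_s <= 0 or self.accel_rate_hz <= 0:
            raise ValueError("tr_s and accel_rate_hz must be positive")
        if self.injection_onset_s + self.injection_duration_s >= self.scan_duration_s:
            raise ValueError("injection must finish before the scan ends")
        if not self.session_schedule:
            raise ValueError("session schedule must be non-empty")
        if self.behavior_baseline_s <= 0 or self.behavior_post_s <= 0:
            raise ValueError("behaviour durations must be positive")

    @property
    def scan_duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    @property
    def behavior_injection_s(self) -> float:
        """Injection time within a behavioural trace (after the baseline)."""
        return self.behavior_baseline_s

    def to_dict(self) -> dict:
        d = asdict(self)
        d["session_schedule"] = [asdict(s) for s in self.session_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sched = d.pop("session_schedule", None)
        cfg = cls(**d) if sched is None else cls(
            session_schedule=[SessionDescriptor(**s) for s in sched], **d
        )
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _default_amplitudes() -> dict[str, float]:
    # percent-signal-change amplitudes of the first drug response; the
    # olivo-cerebellar nodes respond most strongly
    return {
        "ION": 1.0,
        "cerebellum": 1.0,
        "DCN": 0.8,
        "thalamus": 0.6,
        "SMC": 0.3,
        "limbic": 0.2,
        "visual": 0.3,
    }


def _default_gains() -> dict[str, float]:
    # BOLD drift per unit relative heart-rate deviation, percent of
    # baseline; gray > white > CSF
    return {"gray": 3.0, "white": 2.0, "csf": 1.0}


def _default_coupling() -> list[tuple[str, str, float]]:
    # post-injection shared fluctuations (percent signal units) producing
    # the cerebello-thalamic and cerebello-DCN connectivity increase
    return [("cerebellum", "thalamus", 0.35), ("cerebellum", "DCN", 0.30)]


@dataclass
class SessionTruth:
    """Ground-truth generative parameters of one session.

    The drop amplitude of the heart rate and the artifact gains are free
    parameters (the study they emulate reports the bradycardia and BOLD
    drift only graphically).
    """

    roi_amplitude_pct: dict[str, float] = field(default_factory=_default_amplitudes)
    artifact_gain_pct: dict[str, float] = field(default_factory=_default_gains)
    hr_baseline_bpm: float = 120.0
    hr_drop_bpm: float = 40.0
    hr_nadir_s: float = 600.0
    hr_recovery_tau_s: float = 600.0
    hr_rise_tau_s: float = 150.0
    tremor_amplitude: float = 2.0
    tremor_frequency_hz: float = 13.0
    tolerance_decay: float = 0.7
    response_block_s: float = 25.0
    baseline_level: float = 1000.0
    noise_pct: float = 0.5
    roi_fluct_pct: float = 0.25
    coupling: list[tuple[str, str, float]] = field(default_factory=_default_coupling)
    motion_sd: float = 1.0
    sensor_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_baseline_bpm <= 0:
            raise ValueError("heart-rate baseline must be positive")
        if self.hr_drop_bpm < 0 or self.hr_drop_bpm >= self.hr_baseline_bpm:
            raise ValueError("heart-rate drop must be in [0, baseline)")
        if not (0 < self.tolerance_decay <= 1):
            raise ValueError("tolerance decay factor must lie in (0, 1]")
        if self.tremor_frequency_hz <= 0:
            raise ValueError("tremor frequency must be positive")

    def decayed(self, injection_number: int) -> "SessionTruth":
        """Truth for the n-th injection (1-based): response amplitudes,
        tremor amplitude and network coupling all attenuate by
        decay^(injections so far)."""
        if injection_number < 1:
            raise ValueError("injection_number is 1-based")
        f = self.tolerance_decay ** (injection_number - 1)
        out = SessionTruth(**{**asdict(self)})
        out.roi_amplitude_pct = {k: v * f for k, v in self.roi_amplitude_pct.items()}
        out.tremor_amplitude = self.tremor_amplitude * f
        out.coupling = [(a, b, c * f) for (a, b, c) in self.coupling]
        return out

    def as_saline(self) -> "SessionTruth":
        """Null-drug version: no activation, no bradycardia, no coupling."""
        out = SessionTruth(**{**asdict(self)})
        out.roi_amplitude_pct = {k: 0.0 for k in self.roi_amplitude_pct}
        out.hr_drop_bpm = 0.0
        out.tremor_amplitude = 0.0
        out.coupling = []
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupling"] = [list(c) for c in d["coupling"]]
        return d
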