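"""Synthetic-data generator: atlas construction, heart rate, BOLD,
accelerometer sessions and the full experiment bundle."""
import numpy as np
import pytest

from phtremor import (
    ExperimentConfig,
    SessionTruth,
    TremorAnalysis,
    make_atlas,
    simulate_accelerometer,
    simulate_bold_session,
    simulate_experiment,
    simulate_heart_rate,
)
from phtremor.config import ALL_ROIS, NETWORK_ROIS
from phtremor.design import build_design

from conftest import dft_amplitude_oracle


class TestMakeAtlas:
    def test_two_disjoint_blocks(self):
        atlas = make_atlas(
            (8, 8, 8),
            [("a", (0, 2, 0, 2, 0, 2)), ("b", (4, 6, 4, 6, 4, 6))],
        )
        assert set(np.unique(atlas.labels)) == {0, 1, 2}
        assert (atlas.labels == 1).sum() == 8
        assert (atlas.labels == 2).sum() == 8
        assert atlas.label_table == {1: "a", 2: "b"}

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_atlas(
                (8, 8, 8),
                [("a", (0, 4, 0, 4, 0, 4)), ("b", (2, 6, 2, 6, 2, 6))],
            )

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            make_atlas((8, 8, 8), [])

    def test_block_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_atlas((4, 4, 4), [("a", (0, 8, 0, 2, 0, 2))])

    def test_default_atlas_has_network_rois_plus_ion(self, atlas):
        assert len(atlas.roi_names) == 7
        assert set(atlas.roi_names) == set(NETWORK_ROIS) | {"ION"}
        for name in ALL_ROIS:
            assert atlas.roi_mask(name).sum() > 0


class TestHeartRate:
    def test_zero_drop_gives_constant_baseline(self, config):
        truth = SessionTruth(hr_drop_bpm=0.0)
        _, bpm = simulate_heart_rate(config, truth)
        assert np.allclose(bpm, truth.hr_baseline_bpm)

    def test_default_baseline_is_120_bpm(self, config, truth):
        _, bpm = simulate_heart_rate(config, truth)
        assert truth.hr_baseline_bpm == 120.0
        assert bpm[0] == 120.0

    def test_minimum_equals_baseline_minus_drop_at_nadir(self, config):
        # nadir placed inside the scan so the dense grid brackets it
        truth = SessionTruth(hr_baseline_bpm=120.0, hr_drop_bpm=40.0,
                             hr_nadir_s=100.0, hr_rise_tau_s=25.0)
        times, bpm = simulate_heart_rate(config, truth, duration_s=484.0,
                                         sample_rate_hz=100.0)
        i_min = np.argmin(bpm)
        assert bpm[i_min] == pytest.approx(80.0, abs=1e-6)
        assert times[i_min] == pytest.approx(
            config.injection_onset_s + truth.hr_nadir_s, abs=1.0)

    def test_excessive_drop_rejected(self):
        with pytest.raises(ValueError):
            SessionTruth(hr_baseline_bpm=120.0, hr_drop_bpm=130.0)

    def test_constant_before_injection(self, config, truth):
        times, bpm = simulate_heart_rate(config, truth)
        pre = bpm[times <= config.injection_onset_s]
        assert np.allclose(pre, truth.hr_baseline_bpm)


class TestBoldSession:
    def test_noiseless_roi_mean_is_amplitude_times_regressor(self, atlas, config):
        truth = SessionTruth(noise_pct=0.0, roi_fluct_pct=0.0, coupling=[],
                             artifact_gain_pct={"gray": 0.0})
        bold, _ = simulate_bold_session(atlas, config, truth,
                                        rng=np.random.default_rng(0))
        task = build_design(config.n_volumes, config.tr_s,
                            config.injection_onset_s,
                            truth.response_block_s).regressor
        for name, amp in truth.roi_amplitude_pct.items():
            series = bold.data[atlas.roi_mask(name)].mean(axis=0)
            expected = truth.baseline_level * (1.0 + amp / 100.0 * task)
            np.testing.assert_allclose(series, expected, rtol=1e-12)

    def test_same_seed_bit_identical(self, atlas, config, truth):
        a, _ = simulate_bold_session(atlas, config, truth,
                                     rng=np.random.default_rng(42))
        b, _ = simulate_bold_session(atlas, config, truth,
                                     rng=np.random.default_rng(42))
        assert np.array_equal(a.data, b.data)

    def test_default_scan_is_242_volumes_484_s(self, atlas, config, truth):
        bold, _ = simulate_bold_session(atlas, config, truth,
                                        rng=np.random.default_rng(0))
        assert bold.n_volumes == 242
        assert bold.n_volumes * bold.tr_s == 484.0

    def test_saline_has_no_activation_or_bradycardia(self, atlas, config, truth):
        bold, (t, bpm) = simulate_bold_session(
            atlas, config, truth, condition="saline",
            rng=np.random.default_rng(0))
        assert np.allclose(bpm, truth.hr_baseline_bpm)
        # ROI means stay within noise of the flat baseline
        for name in ("ION", "cerebellum"):
            series = bold.data[atlas.roi_mask(name)].mean(axis=0)
            assert abs(series.mean() - truth.baseline_level) < 2.0

    def test_grid_mismatch_rejected(self, config):
        truth = SessionTruth(coupling=[])
        small = make_atlas((4, 4, 4), [("a", (0, 2, 0, 2, 0, 2))])
        bold, _ = simulate_bold_session(small, config, truth,
                                        rng=np.random.default_rng(0))
        assert bold.grid_shape == (4, 4, 4)
        with pytest.raises(ValueError, match="tissue"):
            simulate_bold_session(small, config, truth,
                                  tissue_labels=np.ones((8, 8, 8)),
                                  rng=np.random.default_rng(0))


def _short_cfg(**kw):
    return ExperimentConfig(n_animals=1, behavior_baseline_s=120.0,
                            behavior_post_s=240.0, **kw)


class TestAccelerometer:
    def test_default_rate_100_hz(self, truth):
        cfg = _short_cfg()
        trace = simulate_accelerometer(cfg, truth, session_index=1,
                                       rng=np.random.default_rng(0))
        assert trace.rate_hz == 100.0

    def test_zero_amplitude_indistinguishable_from_baseline(self):
        cfg = _short_cfg()
        truth = SessionTruth(tremor_amplitude=0.0)
        trace = simulate_accelerometer(cfg, truth, session_index=1,
                                       rng=np.random.default_rng(1))
        res = TremorAnalysis(trace, window_s=60.0).fit()
        # normalised window index stays near 1 everywhere
        assert np.all(np.abs(res.windows.index - 1.0) < 0.5)

    def test_spectral_peak_within_one_bin_of_configured_frequency(self, truth):
        cfg = _short_cfg()
        trace = simulate_accelerometer(cfg, truth, session_index=1,
                                       rng=np.random.default_rng(2))
        # a fully developed post-injection bin, via the independent oracle
        n_bin = int(10 * cfg.accel_rate_hz)
        start = int((cfg.behavior_baseline_s + 100.0) * cfg.accel_rate_hz)
        freqs, amp = dft_amplitude_oracle(
            trace.samples[start:start + n_bin], cfg.accel_rate_hz)
        peak_f = freqs[1:][np.argmax(amp[1:])]
        df = freqs[1] - freqs[0]
        assert abs(peak_f - truth.tremor_frequency_hz) <= df + 1e-9

    def test_super_nyquist_frequency_rejected(self):
        cfg = _short_cfg()
        truth = SessionTruth(tremor_frequency_hz=60.0)
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_accelerometer(cfg, truth, session_index=1,
                                   rng=np.random.default_rng(0))

    def test_tolerance_decay_strictly_decreases_true_amplitude(self, truth):
        amps = [truth.decayed(j).tremor_amplitude for j in (1, 2, 3)]
        assert amps[0] > amps[1] > amps[2]


class TestExperiment:
    def test_zero_animals_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(n_animals=0)

    def test_default_schedule_composition(self):
        cfg = ExperimentConfig(n_animals=2, behavior_baseline_s=60.0,
                               behavior_post_s=120.0)
        exp = simulate_experiment(cfg)
        for animal, sessions in exp.animals.items():
            kinds = [s.kind for s in sessions]
            assert kinds.count("fmri_harmaline") == 3
            assert kinds.count("fmri_saline") == 1
            assert kinds.count("behavior") == 3
        # six injections per animal; saline not counted
        inj = [s.injection_number for s in exp.animals["animal01"]
               if s.kind != "fmri_saline"]
        assert sorted(inj) == [1, 2, 3, 4, 5, 6]

    def test_determinism_and_truth_ledger(self):
        cfg = ExperimentConfig(n_animals=1, behavior_baseline_s=60.0,
                               behavior_post_s=120.0, seed=5)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        for (_, sa), (_, sb) in zip(a.sessions(), b.sessions()):
            if sa.bold is not None:
                assert np.array_equal(sa.bold.data, sb.bold.data)
            if sa.accel is not None:
                assert np.array_equal(sa.accel.samples, sb.accel.samples)
        assert a.truth_ledger == b.truth_ledger
        assert "animal01" in a.truth_ledger["animals"]

    def test_saline_truth_is_null(self):
        cfg = ExperimentConfig(n_animals=1, behavior_baseline_s=60.0,
                               behavior_post_s=120.0)
        exp = simulate_experiment(cfg)
        sal = [s for _, s in exp.sessions("fmri_saline")]
        assert sal and all(
            all(v == 0.0 for v in s.truth.roi_amplitude_pct.values())
            and s.truth.hr_drop_bpm == 0.0
            for s in sal
        )
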