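"""Filter chain, clipping detection and epoching."""

import numpy as np
import pandas as pd
import pytest

from mtsdecode.lfp import SessionRecording
from mtsdecode.preprocessing import (
    EpochedData,
    PreprocError,
    PreprocParams,
    detect_clipping,
    epoch,
    preprocess_continuous,
)
from mtsdecode.task import TrialRecord


def make_recording(voltages, fs=1000.0, events=None):
    n_ch = voltages.shape[0]
    ev = events if events is not None else pd.DataFrame(
        {"label": [], "sample_index": [], "trial_id": []}
    )
    return SessionRecording(
        voltages=voltages.astype(np.float32),
        sampling_rate_hz=fs,
        events=ev,
        channel_ids=[f"ch{c:03d}" for c in range(n_ch)],
    )


def trial(tid, outcome="hit", rt=400.0):
    return TrialRecord(
        trial_id=tid, session_id="s", task_type="color",
        sample_color="orange", sample_motion=None,
        test_color="orange", test_motion="up", is_target=True,
        outcome=outcome,
        reaction_time_ms=rt if outcome in ("hit", "false_alarm") else None,
        delay_ms=1000.0,
    )


class TestFilterChain:
    def test_line_frequency_attenuated_at_least_20db(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * 50.0 * t)[None, :], fs)
        out = preprocess_continuous(rec).voltages[0]
        mid = out[len(out) // 4 : -len(out) // 4]
        rms_in = np.sqrt(np.mean(np.sin(2 * np.pi * 50 * t) ** 2))
        rms_out = np.sqrt(np.mean(mid.astype(float) ** 2))
        assert 20 * np.log10(rms_in / rms_out) >= 20.0

    def test_dc_removed_by_high_pass_edge(self):
        rec = make_recording(np.full((2, 30000), 7.3), 1000.0)
        out = preprocess_continuous(rec).voltages
        n = out.shape[1]
        assert np.abs(out[:, n // 3 : 2 * n // 3]).max() < 0.05

    def test_resampling_length_arithmetic(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(1, 4000)), 1000.0)
        out = preprocess_continuous(rec)
        assert out.voltages.shape == (1, 1000)
        assert out.sampling_rate_hz == 250.0

    def test_event_remapping_preserves_relative_latency(self):
        ev = pd.DataFrame(
            {
                "label": ["sample_on", "test_on"],
                "sample_index": [2000, 4404],
                "trial_id": [0, 0],
            }
        )
        rec = make_recording(np.zeros((1, 8000)) + np.random.default_rng(1).normal(size=8000) * 0.1, 1000.0, ev)
        out = preprocess_continuous(rec)
        d_native = (4404 - 2000) * 250.0 / 1000.0
        d_new = out.events.sample_index.iloc[1] - out.events.sample_index.iloc[0]
        assert abs(d_new - d_native) <= 1

    def test_near_idempotent_on_band_limited_resampled_signal(self):
        """A 10+30 Hz signal already at 250 Hz passes the chain unchanged up
        to numerical tolerance (interior samples)."""
        fs = 250.0
        t = np.arange(int(40 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t) + 0.5 * np.sin(2 * np.pi * 30 * t)
        rec = make_recording(x[None, :], fs)
        params = PreprocParams(lowpass_hz=100.0)  # valid low-pass at 250 Hz
        out = preprocess_continuous(rec, params).voltages[0].astype(float)
        interior = slice(int(2 * fs), -int(2 * fs))
        err = np.sqrt(np.mean((out[interior] - x[interior]) ** 2))
        assert err < 0.05 * np.sqrt(np.mean(x[interior] ** 2))

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"bandpass_hz": (0.0, 80.0)}, "band-pass"),
            ({"bandpass_hz": (1.0, 200.0)}, "below lowpass"),
            ({"clip_run_len": 0}, "clip_run_len"),
        ],
    )
    def test_invalid_params(self, kwargs, match):
        with pytest.raises(PreprocError, match=match):
            PreprocParams(**kwargs)

    def test_low_native_rate_rejected(self):
        rec = make_recording(np.zeros((1, 1000)), 250.0)
        with pytest.raises(PreprocError, match="native rate"):
            preprocess_continuous(rec)


class TestClippingDetection:
    PARAMS = PreprocParams(clip_threshold=0.99, clip_run_len=10, rail_uv=500.0)

    def test_sustained_rail_detected(self):
        seg = np.zeros((2, 200))
        seg[1, 100:150] = 500.0
        assert detect_clipping(seg, self.PARAMS) is True

    def test_noise_below_rail_clean(self):
        seg = np.random.default_rng(0).normal(scale=20.0, size=(4, 500))
        assert detect_clipping(seg, self.PARAMS) is False

    def test_single_sample_spike_below_run_length(self):
        seg = np.zeros((1, 100))
        seg[0, 50] = 500.0
        assert detect_clipping(seg, PreprocParams(clip_run_len=3)) is False
        assert detect_clipping(seg, PreprocParams(clip_run_len=1)) is True

    def test_empty_segment_rejected(self):
        with pytest.raises(PreprocError, match="empty"):
            detect_clipping(np.empty((1, 0)))


class TestEpoching:
    @pytest.fixture()
    def recording(self):
        rng = np.random.default_rng(2)
        ev = pd.DataFrame(
            {
                "label": ["test_on", "test_on", "response", "test_on"],
                "sample_index": [500, 1200, 1290, 1900],
                "trial_id": [0, 1, 1, 2],
            }
        )
        return make_recording(rng.normal(size=(3, 2500)), 250.0, ev)

    @pytest.fixture()
    def trials(self):
        return [trial(0, "correct_rejection"), trial(1, "hit", 360.0), trial(2, "hit", 400.0)]

    def test_window_bin_count(self, recording, trials):
        ep = epoch(recording, trials, "test_on", (-200.0, 600.0))
        assert ep.data.shape == (3, 3, 200)
        assert ep.time_ms[0] == -200.0
        assert ep.time_ms[-1] == 596.0
        assert np.allclose(np.diff(ep.time_ms), 4.0)

    def test_button_press_does_not_truncate(self, recording, trials):
        """Trial 1 presses at 360 ms; its epoch still spans the full window."""
        ep = epoch(recording, trials, "test_on", (-100.0, 600.0))
        assert ep.data.shape[2] == 175
        i = list(ep.trial_ids).index(1)
        assert np.isfinite(ep.data[i]).all()

    def test_outcome_filter(self, recording, trials):
        ep = epoch(recording, trials, "test_on", (-100.0, 300.0), outcomes=("hit",))
        assert list(ep.trial_ids) == [1, 2]

    def test_clipped_trial_dropped(self, recording, trials):
        recording.voltages[0, 1200:1260] = 500.0
        ep = epoch(
            recording, trials, "test_on", (-100.0, 300.0),
            reject_clipping=True,
            clip_params=PreprocParams(clip_run_len=5, rail_uv=500.0),
        )
        assert 1 not in ep.trial_ids
        assert {0, 2} <= set(ep.trial_ids)

    def test_window_exceeding_recording_rejected(self, recording, trials):
        with pytest.raises(PreprocError, match="exceeds"):
            epoch(recording, trials, "test_on", (-3000.0, 600.0))

    def test_missing_event_rejected(self, recording):
        with pytest.raises(KeyError):
            epoch(recording, [trial(7)], "test_on", (-100.0, 300.0))

    def test_row_order_matches_trial_ids(self, recording, trials):
        ep = epoch(recording, trials, "test_on", (-100.0, 300.0))
        for row, tid in enumerate(ep.trial_ids):
            idx = recording.event_index(int(tid), "test_on")
            expect = recording.voltages[:, idx - 25 : idx + 75]
            assert np.array_equal(ep.data[row], expect)

    def test_epochs_hdf5_roundtrip_lossless(self, recording, trials, tmp_path):
        from mtsdecode.io import read_epochs_h5, write_epochs_h5

        ep = epoch(recording, trials, "test_on", (-100.0, 300.0))
        write_epochs_h5(ep, tmp_path / "e.h5")
        back = read_epochs_h5(tmp_path / "e.h5")
        assert np.array_equal(back.data, ep.data)
        assert np.array_equal(back.time_ms, ep.time_ms)
        assert back.lock_event == ep.lock_event
        assert list(back.trial_ids) == list(ep.trial_ids)
        assert back.channel_ids == ep.channel_ids

    def test_nonuniform_time_axis_rejected(self):
        with pytest.raises(PreprocError, match="uniform"):
            EpochedData(
                data=np.zeros((1, 1, 3), dtype=np.float32),
                time_ms=np.array([0.0, 4.0, 12.0]),
                lock_event="test_on",
                trial_ids=np.array([0]),
                channel_ids=["ch000"],
            )
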