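"""Continuous-signal cleaning and event-locked epoching.

The filter chain is applied in a fixed order: 50 Hz notch, 150 Hz low-pass,
polyphase resampling to 250 Hz, then a 1–80 Hz band-pass.  All filters are
zero-phase (forward-backward IIR), so the chain does not shift latencies —
a prerequisite for onset estimation downstream.  Event sample indices are
remapped to the new rate; epochs are fixed windows around a locking event
and are never truncated at the response time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .lfp import SessionRecording
from .task import TrialRecord

logger = logging.getLogger(__name__)


class PreprocError(ValueError):
    """Raised for invalid preprocessing parameters or inputs."""


@dataclass(frozen=True)
class PreprocParams:
    """Filter-chain parameters.

    ``clip_threshold`` is a fraction of the amplifier rail voltage;
    a channel counts as clipped when its magnitude stays at or above
    ``clip_threshold * rail_uv`` for at least ``clip_run_len`` consecutive
    samples.
    """

    notch_hz: float = 50.0
    notch_q: float = 35.0
    lowpass_hz: float = 150.0
    resample_hz: float = 250.0
    bandpass_hz: tuple[float, float] = (1.0, 80.0)
    filter_order: int = 4
    clip_threshold: float = 0.99
    clip_run_len: int = 5
    rail_uv: float = 500.0

    def __post_init__(self) -> None:
        lo, hi = self.bandpass_hz
        if not 0 < lo < hi:
            raise PreprocError(f"invalid band-pass {self.bandpass_hz}")
        if hi >= self.lowpass_hz:
            raise PreprocError("band-pass upper edge must be below lowpass_hz")
        if self.clip_run_len < 1:
            raise PreprocError("clip_run_len must be >= 1")


def preprocess_continuous(
    recording: SessionRecording, params: PreprocParams = PreprocParams()
) -> SessionRecording:
    """Apply notch → low-pass → resample → band-pass, remapping events.

    All stages are zero-phase; the output recording is at
    ``params.resample_hz`` with event indices rounded to the nearest new
    sample (relative latencies preserved within one output sample).
    """
    fs = recording.sampling_rate_hz
    if recording.n_samples == 0:
        raise PreprocError("empty recording")
    if fs <= 2 * params.lowpass_hz:
        raise PreprocError(
            f"native rate {fs} Hz must exceed twice the low-pass edge "
            f"({params.lowpass_hz} Hz)"
        )
    if params.resample_hz > fs:
        raise PreprocError("resample_hz must not exceed the native rate")

    x = np.asarray(recording.voltages, dtype=np.float64)

    # 1) line-noise notch
    b, a = sps.iirnotch(params.notch_hz, params.notch_q, fs=fs)
    x = sps.filtfilt(b, a, x, axis=1)

    # 2) anti-alias low-pass at the native rate
    sos = sps.butter(params.filter_order, params.lowpass_hz, btype="low", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)

    # 3) polyphase resampling
    frac = Fraction(params.resample_hz / fs).limit_denominator(1000)
    if frac != 1:
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    new_fs = params.resample_hz

    # 4) band-pass at the analysis rate
    sos = sps.butter(
        params.filter_order, params.bandpass_hz, btype="bandpass", fs=new_fs, output="sos"
    )
    x = sps.sosfiltfilt(sos, x, axis=1)

    scale = new_fs / fs
    events = recording.events.copy()
    events["sample_index"] = np.rint(events["sample_index"] * scale).astype(int)
    events["sample_index"] = events["sample_index"].clip(0, x.shape[1] - 1)
    return SessionRecording(
        voltages=x.astype(np.float32),
        sampling_rate_hz=new_fs,
        events=events,
        channel_ids=list(recording.channel_ids),
    )


def detect_clipping(
    segment: np.ndarray, params: PreprocParams = PreprocParams(), rail_uv: float | None = None
) -> bool:
    """True iff any channel sits at/above the rail for a run of samples.

    ``segment`` is (channels, samples) or (samples,).  The criterion is
    ``|v| >= clip_threshold * rail`` for at least ``clip_run_len``
    consecutive samples.
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    if seg.size == 0:
        raise PreprocError("empty segment")
    rail = params.rail_uv if rail_uv is None else rail_uv
    pinned = np.abs(seg) >= params.clip_threshold * rail
    if params.clip_run_len == 1:
        return bool(pinned.any())
    k = params.clip_run_len
    # a run of k pinned samples exists iff a moving sum reaches k
    kernel = np.ones(k, dtype=int)
    for row in pinned.astype(int):
        if row.sum() < k:
            continue
        if np.convolve(row, kernel, mode="valid").max() >= k:
            return True
    return False


@dataclass
class EpochedData:
    """Event-locked voltage epochs: trials × channels × time.

    ``time_ms`` holds bin centers relative to the locking event (0 ms = the
    event sample); spacing equals ``1000 / rate``.
    """

    data: np.ndarray                 # (n_trials, n_channels, n_bins) float32
    time_ms: np.ndarray              # (n_bins,)
    lock_event: str
    trial_ids: np.ndarray            # (n_trials,)
    channel_ids: list[str]

    def __post_init__(self) -> None:
        if len(np.unique(self.trial_ids)) != len(self.trial_ids):
            raise PreprocError("trial_ids must be unique")
        d = np.diff(self.time_ms)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise PreprocError("time axis must be strictly increasing and uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def bin_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def select(self, mask: np.ndarray) -> "EpochedData":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return EpochedData(
            data=self.data[idx],
            time_ms=self.time_ms.copy(),
            lock_event=self.lock_event,
            trial_ids=self.trial_ids[idx],
            channel_ids=list(self.channel_ids),
        )

    def select_channels(self, channels: Sequence[int]) -> "EpochedData":
        channels = list(channels)
        return EpochedData(
            data=self.data[:, channels, :],
            time_ms=self.time_ms.copy(),
            lock_event=self.lock_event,
            trial_ids=self.trial_ids.copy(),
            channel_ids=[self.channel_ids[c] for c in channels],
        )


def epoch(
    recording: SessionRecording,
    trial_records: Sequence[TrialRecord],
    lock_event: str = "test_on",
    window_ms: tuple[float, float] = (-200.0, 600.0),
    *,
    outcomes: Optional[Sequence[str]] = None,
    reject_clipping: bool = False,
    clip_params: PreprocParams = PreprocParams(),
) -> EpochedData:
    """Cut fixed windows around ``lock_event`` for the requested trials.

    ``window_ms = (t0, t1)`` produces ``(t1 - t0) / bin`` bins covering
    ``[t0, t1)``.  Trials whose outcome is not in ``outcomes`` (when given)
    are skipped; trials failing the clipping check (when enabled) are
    dropped and logged.  Button presses never truncate an epoch — the full
    window is always returned.
    """
    fs = recording.sampling_rate_hz
    step_ms = 1000.0 / fs
    lo = int(round(window_ms[0] / step_ms))
    hi = int(round(window_ms[1] / step_ms))
    if hi <= lo:
        raise PreprocError(f"empty window {window_ms}")
    n_bins = hi - lo
    time_ms = (np.arange(lo, hi)) * step_ms

    keep, segs = [], []
    for rec in trial_records:
        if rec.outcome == "aborted":
            continue
        if outcomes is not None and rec.outcome not in outcomes:
            continue
        idx = recording.event_index(rec.trial_id, lock_event)
        a, b = idx + lo, idx + hi
        if a < 0 or b > recording.n_samples:
            raise PreprocError(
                f"window {window_ms} around trial {rec.trial_id} exceeds the recording"
            )
        seg = recording.voltages[:, a:b]
        if reject_clipping and detect_clipping(seg, clip_params):
            logger.info("trial %d dropped: clipping detected", rec.trial_id)
            continue
        keep.append(rec.trial_id)
        segs.append(np.asarray(seg, dtype=np.float32))

    data = (
        np.stack(segs, axis=0)
        if segs
        else np.empty((0, recording.n_channels, n_bins), dtype=np.float32)
    )
    return EpochedData(
        data=data,
        time_ms=time_ms,
        lock_event=lock_event,
        trial_ids=np.asarray(keep, dtype=int),
        channel_ids=list(recording.channel_ids),
    )
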