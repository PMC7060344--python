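"""Synthesis of continuous multichannel LFP with known injected effects.

The voltage model is additive::

    voltage = 1/f noise (per channel) + shared common-mode 1/f source
            + 50 Hz line component
            + stereotyped evoked response at every sample/test onset
            + injected effect components

Effect components are the ground truth that downstream decoding is asked to
recover.  Each component is a plateau waveform with raised-cosine ramps,
locked to a trial event, weighted across channels, and gated by what it is
selective for:

* ``color_identity`` / ``motion_identity`` — a distinct channel pattern per
  feature level (random orthonormal directions, unit per-channel RMS), so
  the four levels are linearly separable with a known latency;
* ``color_match`` / ``motion_match`` — present only on trials where the test
  matches the searched-for feature (sample must carry that feature);
* ``motor_response`` — locked to the button-press event.

Component waveforms are a Hann-ramp plateau envelope multiplying a
phase-locked sinusoidal carrier (default 24 Hz).  The carrier keeps the
component inside the downstream 1–80 Hz analysis band: a raw plateau has
most of its energy near DC, and a zero-phase 1 Hz high-pass would smear
that energy symmetrically in time, leaking feature information into
pre-stimulus bins and corrupting onset estimates.

The realized per-trial onsets and channel patterns are returned as
:class:`GroundTruth`, sufficient to re-render the noiseless effect signal
and subtract it from the voltages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import TrialRecord

SELECTIVITIES = (
    "color_identity",
    "motion_identity",
    "color_match",
    "motion_match",
    "motor_response",
)


class SignalSpecError(ValueError):
    """Raised for inconsistent signal specifications."""


@dataclass(frozen=True)
class EffectComponent:
    """One injectable signal component with a known latency.

    ``latency_ms`` is relative to the locking event; ``duration_ms`` is the
    total extent including two ``ramp_ms`` raised-cosine ramps.  ``amplitude``
    is the plateau peak in the same units as the noise amplitude (µV).
    ``channel_weights`` (length ``n_channels``) defaults to all ones.
    ``carrier_hz`` modulates the envelope with a phase-locked sinusoid so
    the component lies inside the analysis band (0 disables the carrier and
    yields the raw envelope).  ``outcome_restrict`` optionally limits the
    component to trials with the given behavioral outcomes.
    """

    selectivity: str
    latency_ms: float
    duration_ms: float
    amplitude: float
    channel_weights: Optional[np.ndarray] = None
    ramp_ms: float = 20.0
    carrier_hz: float = 24.0
    lock: str = "test_on"
    outcome_restrict: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.selectivity not in SELECTIVITIES:
            raise SignalSpecError(f"unknown selectivity {self.selectivity!r}")
        if self.latency_ms < 0:
            raise SignalSpecError("latency_ms must be >= 0")
        if self.duration_ms <= 0:
            raise SignalSpecError("duration_ms must be > 0")
        if self.lock not in ("sample_on", "test_on", "response"):
            raise SignalSpecError(f"unknown lock event {self.lock!r}")


@dataclass(frozen=True)
class SignalSpec:
    """Noise model, evoked response and effect components of a session."""

    n_channels: int = 24
    sampling_rate_hz: float = 1000.0
    noise_amp: float = 1.0           # per-channel 1/f SD, µV
    common_mode_amp: float = 0.5     # shared 1/f source SD, µV
    line_noise_amp: float = 0.2      # 50 Hz amplitude, µV
    line_freq_hz: float = 50.0
    evoked_amp: float = 2.0          # stereotyped onset response peak, µV
    evoked_latency_ms: float = 60.0
    evoked_width_ms: float = 30.0    # Gaussian SD
    effects: tuple[EffectComponent, ...] = ()
    pre_sample_ms: float = 300.0     # fixation before sample onset
    iti_ms: float = 400.0            # inter-trial interval
    abort_span_ms: float = 500.0     # recording time consumed by an abort

    def __post_init__(self) -> None:
        if not 1 <= self.n_channels <= 96:
            raise SignalSpecError("n_channels must be in 1..96")
        for c in self.effects:
            if c.channel_weights is not None and len(c.channel_weights) != self.n_channels:
                raise SignalSpecError(
                    f"channel_weights length {len(c.channel_weights)} != "
                    f"n_channels {self.n_channels}"
                )


@dataclass
class SessionRecording:
    """Continuous voltages plus event markers for one session."""

    voltages: np.ndarray             # (n_channels, n_samples), µV
    sampling_rate_hz: float
    events: pd.DataFrame             # columns: label, sample_index, trial_id
    channel_ids: list[str]

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    def event_index(self, trial_id: int, label: str) -> int:
        sel = self.events[
            (self.events.trial_id == trial_id) & (self.events.label == label)
        ]
        if sel.empty:
            raise KeyError(f"no {label!r} event for trial {trial_id}")
        return int(sel.sample_index.iloc[0])


@dataclass
class RealizedComponent:
    """An effect component together with everything realized per trial."""

    component: EffectComponent
    # one row per trial the component was applied to
    trial_ids: np.ndarray            # (n_applied,)
    onset_samples: np.ndarray        # (n_applied,) absolute sample index
    patterns: np.ndarray             # (n_applied, n_channels) signed weights


@dataclass
class GroundTruth:
    """Sufficient record to re-render the noiseless injected effect signal."""

    realized: list[RealizedComponent]
    behavior_seed_note: str
    master_seed: int
    n_channels: int
    n_samples: int
    sampling_rate_hz: float


def _waveform(
    duration_ms: float, ramp_ms: float, fs: float, carrier_hz: float = 0.0
) -> np.ndarray:
    """Plateau with raised-cosine on/off ramps, peak 1, optional carrier."""
    n = max(int(round(duration_ms * fs / 1000.0)), 2)
    t = np.arange(n) * 1000.0 / fs
    ramp = min(ramp_ms, duration_ms / 2.0)
    w = np.ones(n)
    if ramp > 0:
        up = t < ramp
        w[up] = 0.5 * (1 - np.cos(np.pi * t[up] / ramp))
        dn = t > duration_ms - ramp
        w[dn] = 0.5 * (1 - np.cos(np.pi * (duration_ms - t[dn]) / ramp))
    if carrier_hz > 0:
        w = w * np.sin(2 * np.pi * carrier_hz * t / 1000.0)
    return w


def _one_over_f(n_samples: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise trace with a 1/f power spectrum (FFT shaping).

    Synthesized at the next fast FFT length and truncated, which leaves the
    spectrum essentially unchanged while avoiding slow prime-length
    transforms on long sessions.
    """
    from scipy.fft import next_fast_len

    n_fft = next_fast_len(n_samples, real=True)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** -0.5
    spec = shape * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    x = np.fft.irfft(spec, n=n_fft)[:n_samples]
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_lfp(
    trial_records: Sequence[TrialRecord],
    spec: SignalSpec,
    seed: int,
    *,
    sample_dur_ms: float = 1000.0,
    test_dur_ms: float = 250.0,
    response_window_ms: float = 600.0,
) -> tuple[SessionRecording, GroundTruth]:
    """Render one continuous session for the given trial records.

    Trials are laid out back to back with ``spec.iti_ms`` between them.
    Aborted trials receive a sample_on event only and a short segment;
    every other trial gets sample_on and test_on events, plus a response
    event iff a button press occurred.  Identical inputs and seed give
    bit-identical output.
    """
    if not trial_records:
        raise ValueError("no trial records")
    fs = spec.sampling_rate_hz
    rng = np.random.default_rng(seed)

    # --- timeline -----------------------------------------------------
    ev_label: list[str] = []
    ev_index: list[int] = []
    ev_trial: list[int] = []
    cursor = int(round(spec.iti_ms * fs / 1000.0))
    for rec in trial_records:
        sample_on = cursor + int(round(spec.pre_sample_ms * fs / 1000.0))
        ev_label.append("sample_on"); ev_index.append(sample_on); ev_trial.append(rec.trial_id)
        if rec.outcome == "aborted":
            cursor = sample_on + int(round(spec.abort_span_ms * fs / 1000.0))
        else:
            test_on = sample_on + int(round((sample_dur_ms + rec.delay_ms) * fs / 1000.0))
            ev_label.append("test_on"); ev_index.append(test_on); ev_trial.append(rec.trial_id)
            if rec.reaction_time_ms is not None:
                resp = test_on + int(round(rec.reaction_time_ms * fs / 1000.0))
                ev_label.append("response"); ev_index.append(resp); ev_trial.append(rec.trial_id)
            cursor = test_on + int(round((test_dur_ms + response_window_ms) * fs / 1000.0))
        cursor += int(round(spec.iti_ms * fs / 1000.0))
    n_samples = cursor + int(round(spec.iti_ms * fs / 1000.0))
    events = pd.DataFrame(
        {"label": ev_label, "sample_index": ev_index, "trial_id": ev_trial}
    )

    # --- noise --------------------------------------------------------
    volts = np.empty((spec.n_channels, n_samples))
    for ch in range(spec.n_channels):
        volts[ch] = spec.noise_amp * _one_over_f(n_samples, fs, rng)
    if spec.common_mode_amp > 0:
        volts += spec.common_mode_amp * _one_over_f(n_samples, fs, rng)
    if spec.line_noise_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n_samples) / fs
        volts += spec.line_noise_amp * np.sin(2 * np.pi * spec.line_freq_hz * t + phase)

    # --- evoked responses at every stimulus onset ---------------------
    if spec.evoked_amp != 0:
        half = int(round(3 * spec.evoked_width_ms * fs / 1000.0))
        tt = (np.arange(-half, half + 1)) * 1000.0 / fs
        kernel = spec.evoked_amp * np.exp(
            -0.5 * ((tt - 0.0) / spec.evoked_width_ms) ** 2
        )
        lat = int(round(spec.evoked_latency_ms * fs / 1000.0))
        onsets = events.sample_index[events.label.isin(["sample_on", "test_on"])]
        for idx in onsets:
            _add_segment(volts, kernel[None, :], idx + lat - half)

    # --- injected effect components -----------------------------------
    by_id = {r.trial_id: r for r in trial_records}
    ev_lookup = {
        (int(r.trial_id), r.label): int(r.sample_index) for r in events.itertuples()
    }
    realized: list[RealizedComponent] = []
    for comp in spec.effects:
        realized.append(
            _apply_component(volts, comp, by_id, ev_lookup, spec, fs, rng)
        )

    recording = SessionRecording(
        voltages=volts.astype(np.float32),
        sampling_rate_hz=fs,
        events=events,
        channel_ids=[f"ch{c:03d}" for c in range(spec.n_channels)],
    )
    gt = GroundTruth(
        realized=realized,
        behavior_seed_note="effects rendered by synthesize_lfp",
        master_seed=seed,
        n_channels=spec.n_channels,
        n_samples=n_samples,
        sampling_rate_hz=fs,
    )
    return recording, gt


def _add_segment(volts: np.ndarray, seg: np.ndarray, start: int) -> bool:
    """Add ``seg`` (channels x len) at ``start``, clipping to bounds.

    Returns True when clipping occurred."""
    n = volts.shape[1]
    length = seg.shape[1]
    lo, hi = max(start, 0), min(start + length, n)
    if lo >= hi:
        return True
    volts[:, lo:hi] += seg[:, lo - start : hi - start]
    return lo != start or hi != start + length


def _feature_level(rec: TrialRecord, selectivity: str, lock: str) -> Optional[str]:
    if selectivity == "color_identity":
        return rec.test_color if lock == "test_on" else rec.sample_color
    if selectivity == "motion_identity":
        return rec.test_motion if lock == "test_on" else rec.sample_motion
    return None


def _component_applies(rec: TrialRecord, comp: EffectComponent) -> bool:
    if rec.outcome == "aborted":
        return False
    if comp.outcome_restrict is not None and rec.outcome not in comp.outcome_restrict:
        return False
    if comp.selectivity == "color_match":
        return rec.spec.color_match is True
    if comp.selectivity == "motion_match":
        return rec.spec.motion_match is True
    if comp.selectivity == "motor_response":
        return rec.reaction_time_ms is not None
    return True


def _apply_component(
    volts: np.ndarray,
    comp: EffectComponent,
    by_id: dict[int, TrialRecord],
    ev_lookup: dict[tuple[int, str], int],
    spec: SignalSpec,
    fs: float,
    rng: np.random.Generator,
) -> RealizedComponent:
    weights = (
        np.ones(spec.n_channels)
        if comp.channel_weights is None
        else np.asarray(comp.channel_weights, dtype=float)
    )
    wave = _waveform(comp.duration_ms, comp.ramp_ms, fs, comp.carrier_hz)
    lat = int(round(comp.latency_ms * fs / 1000.0))

    # one channel pattern per feature level, drawn once per component:
    # random orthonormal directions scaled to unit per-channel RMS, so the
    # levels are guaranteed distinct and the amplitude scale is comparable
    # to an all-ones pattern
    level_signs: dict[str, np.ndarray] = {}
    if comp.selectivity in ("color_identity", "motion_identity"):
        levels = sorted(
            {
                lvl
                for rec in by_id.values()
                if (lvl := _feature_level(rec, comp.selectivity, comp.lock)) is not None
            }
        )
        n_lvl = len(levels)
        gauss = rng.normal(size=(spec.n_channels, max(n_lvl, 1)))
        if spec.n_channels >= n_lvl > 0:
            q, _ = np.linalg.qr(gauss)
            basis = q[:, :n_lvl].T
        else:
            basis = gauss.T[:n_lvl]
            basis /= np.linalg.norm(basis, axis=1, keepdims=True)
        for lvl, direction in zip(levels, basis):
            level_signs[lvl] = direction * np.sqrt(spec.n_channels)

    lock = "response" if comp.selectivity == "motor_response" else comp.lock
    trial_ids, onsets, patterns = [], [], []
    clipped = False
    for tid, rec in by_id.items():
        if not _component_applies(rec, comp):
            continue
        key = (tid, lock)
        if key not in ev_lookup:
            continue
        pattern = comp.amplitude * weights
        lvl = _feature_level(rec, comp.selectivity, comp.lock)
        if lvl is not None:
            if lvl not in level_signs:
                continue
            pattern = pattern * level_signs[lvl]
        onset = ev_lookup[key] + lat
        seg = pattern[:, None] * wave[None, :]
        clipped |= _add_segment(volts, seg, onset)
        trial_ids.append(tid)
        onsets.append(onset)
        patterns.append(pattern)
    if clipped:
        warnings.warn(
            f"effect component {comp.selectivity!r} extended past the recording "
            "bounds and was clipped",
            stacklevel=3,
        )
    return RealizedComponent(
        component=comp,
        trial_ids=np.asarray(trial_ids, dtype=int),
        onset_samples=np.asarray(onsets, dtype=int),
        patterns=np.asarray(patterns, dtype=float).reshape(-1, spec.n_channels),
    )


def render_effects(ground_truth: GroundTruth) -> np.ndarray:
    """Re-render the noiseless sum of all injected effect components.

    Subtracting the result from the synthesized voltages removes every
    decodable feature signal the generator injected.
    """
    out = np.zeros((ground_truth.n_channels, ground_truth.n_samples))
    fs = ground_truth.sampling_rate_hz
    for rc in ground_truth.realized:
        wave = _waveform(
            rc.component.duration_ms, rc.component.ramp_ms, fs, rc.component.carrier_hz
        )
        for onset, pattern in zip(rc.onset_samples, rc.patterns):
            _add_segment(out, pattern[:, None] * wave[None, :], int(onset))
    return out
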