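"""Deterministic EEG conditioning: reference, filter, resample, epoch, reject.

The stage order is fixed by the pipeline driver: mastoid re-referencing,
zero-phase Butterworth band-pass on the continuous data, downsampling,
epoch extraction around key-press events, then amplitude-threshold
rejection at the frontocentral region of interest.  No baseline
correction is applied anywhere; the preparatory negativity of interest
has no well-defined pre-onset baseline in this design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import EpochSet, Montage, TrialRecord, RP_ROI, MASTOIDS, time_grid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    highpass_hz: float = 0.05
    lowpass_hz: float = 30.0
    filter_order: int = 8          # design order, applied forward-backward
    target_rate_hz: float = 200.0
    rejection_threshold_uv: float = 120.0
    rejection_channels: tuple[str, ...] = RP_ROI
    mastoid_channels: tuple[str, ...] = MASTOIDS
    epoch_window_s: tuple[float, float] = (-1.0, 0.5)
    baseline: None = None          # fixed: no baseline correction

    def __post_init__(self) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass < lowpass")
        if self.rejection_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")
        if self.baseline is not None:
            raise ValueError("baseline correction is not supported by design")


@dataclass
class Recording:
    """Continuous channels x samples array (µV)."""

    data: np.ndarray
    montage: Montage
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.montage.channels):
            raise ValueError("data rows must match montage channels")


def rereference(recording: Recording, mastoid_channels=MASTOIDS) -> Recording:
    """Subtract the mastoid average from every channel."""
    idx = recording.montage.index(mastoid_channels)
    ref = recording.data[idx].mean(axis=0, keepdims=True)
    return replace(recording, data=recording.data - ref)


def bandpass_zero_phase(recording: Recording, config: PreprocessConfig) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass on continuous data.

    Implemented as cascaded high-pass and low-pass sections in
    second-order-section form: a single band-pass design with a cutoff
    ratio of ~1e-4 relative to Nyquist is numerically unreliable.
    """
    nyq = recording.sampling_rate_hz / 2
    if config.lowpass_hz >= nyq:
        raise ValueError("lowpass cutoff must be below Nyquist")
    data = recording.data
    for cutoff, btype in (
        (config.highpass_hz, "highpass"),
        (config.lowpass_hz, "lowpass"),
    ):
        sos = signal.butter(
            config.filter_order,
            cutoff,
            btype=btype,
            fs=recording.sampling_rate_hz,
            output="sos",
        )
        poles = signal.sos2zpk(sos)[1]
        if np.any(np.abs(poles) >= 1):
            raise ValueError(
                "unstable filter design; use a second-order-section implementation"
            )
        data = signal.sosfiltfilt(sos, data, axis=-1)
    return replace(recording, data=data)


def bandpass_frequency_response(
    config: PreprocessConfig, freqs_hz: np.ndarray, sampling_rate_hz: float
) -> np.ndarray:
    """Effective magnitude response of the zero-phase chain.

    Forward-backward application squares each section's magnitude
    response; the phase is identically zero.
    """
    gain = np.ones(len(np.atleast_1d(freqs_hz)))
    for cutoff, btype in (
        (config.highpass_hz, "highpass"),
        (config.lowpass_hz, "lowpass"),
    ):
        sos = signal.butter(
            config.filter_order, cutoff, btype=btype, fs=sampling_rate_hz,
            output="sos",
        )
        _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=sampling_rate_hz)
        gain *= np.abs(h) ** 2
    return gain


def resample(recording: Recording, target_rate_hz: float) -> Recording:
    """Polyphase resampling onto a uniform grid at the target rate."""
    if target_rate_hz > recording.sampling_rate_hz:
        raise ValueError("target rate exceeds native rate")
    if target_rate_hz == recording.sampling_rate_hz:
        return recording
    frac = (
        math.gcd(int(target_rate_hz * 1000), int(recording.sampling_rate_hz * 1000)),
    )[0]
    up = int(target_rate_hz * 1000) // frac
    down = int(recording.sampling_rate_hz * 1000) // frac
    data = signal.resample_poly(recording.data, up, down, axis=-1, padtype="line")
    return replace(recording, data=data, sampling_rate_hz=target_rate_hz)


def extract_epochs(
    recording: Recording,
    events: pd.DataFrame,
    window_s: tuple[float, float] = (-1.0, 0.5),
    event_rate_hz: float | None = None,
) -> tuple[EpochSet, int]:
    """Slice epochs on the closed window [lo, hi] around each event.

    ``events`` must carry ``event_sample`` (at ``event_rate_hz``, default
    the recording's rate) plus the trial metadata columns.  t = 0 is the
    event sample itself.  Events whose window leaves the recording are
    dropped; the count of drops is returned and logged.
    """
    rate = recording.sampling_rate_hz
    if event_rate_hz is None:
        event_rate_hz = rate
    lo, hi = window_s
    times = time_grid(window_s, rate)
    n_lo = int(round(lo * rate))
    n_len = len(times)
    n_total = recording.data.shape[1]

    data_rows, trials, dropped = [], [], 0
    for _, row in events.iterrows():
        center = int(round(row["event_sample"] * rate / event_rate_hz))
        s0 = center + n_lo
        if s0 < 0 or s0 + n_len > n_total:
            dropped += 1
            continue
        data_rows.append(recording.data[:, s0 : s0 + n_len])
        trials.append(
            TrialRecord(
                participant_id=int(row["participant_id"]),
                condition=row["condition"],
                sequence_length=int(row["sequence_length"]),
                move_position=int(row["move_position"]),
                rt_s=float(row["rt_s"]),
                epoch_index=len(trials),
            )
        )
    if dropped:
        logger.warning("extract_epochs: dropped %d events at recording edges", dropped)
    data = (
        np.array(data_rows)
        if data_rows
        else np.empty((0, len(recording.montage.channels), n_len))
    )
    return (
        EpochSet(
            data=data,
            times_s=times,
            montage=recording.montage,
            trials=trials,
            sampling_rate_hz=rate,
        ),
        dropped,
    )


def reject_artifacts(
    epochs: EpochSet,
    threshold_uv: float = 120.0,
    channels=RP_ROI,
) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs whose amplitude exceeds ±threshold on any listed channel.

    Returns the retained epochs and a boolean mask (True = rejected).
    """
    idx = epochs.montage.index(channels)
    rejected = (np.abs(epochs.data[:, idx, :]) > threshold_uv).any(axis=(1, 2))
    kept = epochs.select(~rejected)
    if rejected.any():
        logger.info(
            "reject_artifacts: removed %d/%d epochs (> %.0f µV)",
            int(rejected.sum()),
            len(rejected),
            threshold_uv,
        )
    return kept, rejected


def preprocess_recording(
    recording: Recording,
    events: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> tuple[EpochSet, dict]:
    """Full conditioning chain in the fixed order:
    reference -> filter -> downsample -> epoch -> reject."""
    config = PreprocessConfig() if config is None else config
    native_rate = recording.sampling_rate_hz
    rec = rereference(recording, config.mastoid_channels)
    rec = bandpass_zero_phase(rec, config)
    rec = resample(rec, config.target_rate_hz)
    epochs, dropped = extract_epochs(
        rec, events, config.epoch_window_s, event_rate_hz=native_rate
    )
    kept, rejected = reject_artifacts(
        epochs, config.rejection_threshold_uv, config.rejection_channels
    )
    log = {
        "n_events": len(events),
        "n_dropped_edge": dropped,
        "n_rejected": int(rejected.sum()),
        "n_kept": len(kept.trials),
        "baseline": "none",
        "stage_order": ["rereference", "bandpass", "resample", "epoch", "reject"],
    }
    return kept, log
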