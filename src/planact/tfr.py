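"""Time-frequency decomposition and beta-band (13-30 Hz) power.

Power is estimated by complex convolution with a Hanning-tapered
exponential of fixed 0.4 s length at every frequency (the single-taper
degenerate case of windowed multitaper convolution).  The taper is
normalized so that a pure sinusoid of amplitude A yields power A² at its
frequency; only ratios and differences of power are interpreted, so the
convention does not affect inference.  Samples within half a window of
either epoch edge are invalid and set to NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .simulate import EpochSet, BETA_ROI

DEFAULT_FREQS = np.arange(1.0, 36.0)
BETA_BAND = (13.0, 30.0)


@dataclass
class TfrPower:
    """Trials x channels x freqs x time power (µV²) with edge-validity mask."""

    power: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    channels: tuple
    window_s: float
    valid_mask: np.ndarray          # per-time boolean, False = edge-invalid
    sampling_rate_hz: float
    trials: list = field(default_factory=list)

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.channels.index(n) for n in names])
        except ValueError as exc:
            raise KeyError(f"channel not in TFR: {exc}") from exc


@dataclass
class BandPowerSeries:
    """Band- and ROI-averaged power series (µV²), trials x time."""

    power: np.ndarray
    times_s: np.ndarray
    band_hz: tuple
    roi: tuple
    trials: list = field(default_factory=list)


def _taper_kernel(freq_hz: float, window_s: float, rate_hz: float) -> np.ndarray:
    """Hanning-windowed complex exponential, amplitude-normalized."""
    n = int(round(window_s * rate_hz))
    n += 1 - n % 2                      # odd length centers the kernel
    k = np.arange(n) - n // 2
    taper = np.hanning(n)
    kernel = taper * np.exp(-2j * np.pi * freq_hz * k / rate_hz)
    # 2/sum(taper): a unit-amplitude sinusoid at freq maps to |X| = 1.
    return kernel * (2.0 / taper.sum())


def tfr_hanning_convolution(
    epochs: EpochSet,
    freqs_hz: np.ndarray = DEFAULT_FREQS,
    window_s: float = 0.4,
    mask: bool = True,
) -> TfrPower:
    """Fixed-window Hanning convolution power at each frequency."""
    rate = epochs.sampling_rate_hz
    n_t = epochs.data.shape[-1]
    if int(round(window_s * rate)) >= n_t:
        raise ValueError("taper window must be shorter than the epoch")
    if rate < 2 * float(np.max(freqs_hz)):
        raise ValueError("sampling rate below Nyquist for requested frequencies")
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    n_trials, n_ch, _ = epochs.data.shape
    power = np.empty((n_trials, n_ch, len(freqs_hz), n_t))
    for fi, f in enumerate(freqs_hz):
        kernel = _taper_kernel(f, window_s, rate)
        conv = fftconvolve(
            epochs.data.astype(complex), kernel[None, None, :], mode="same", axes=2
        )
        power[:, :, fi, :] = np.abs(conv) ** 2
    tfr = TfrPower(
        power=power,
        freqs_hz=freqs_hz,
        times_s=epochs.times_s,
        channels=tuple(epochs.montage.channels),
        window_s=window_s,
        valid_mask=np.ones(n_t, dtype=bool),
        sampling_rate_hz=rate,
        trials=list(epochs.trials),
    )
    return mask_edges(tfr, window_s) if mask else tfr


def mask_edges(tfr: TfrPower, window_s: float | None = None) -> TfrPower:
    """NaN out samples within half a taper window of either epoch edge."""
    window_s = tfr.window_s if window_s is None else window_s
    times = tfr.times_s
    half = window_s / 2
    invalid = (times < times[0] + half) | (times > times[-1] - half)
    power = tfr.power.copy()
    power[..., invalid] = np.nan
    return TfrPower(
        power=power,
        freqs_hz=tfr.freqs_hz,
        times_s=times,
        channels=tfr.channels,
        window_s=tfr.window_s,
        valid_mask=tfr.valid_mask & ~invalid,
        sampling_rate_hz=tfr.sampling_rate_hz,
        trials=tfr.trials,
    )


def band_roi_average(
    tfr: TfrPower,
    band: tuple = BETA_BAND,
    roi: Sequence[str] = BETA_ROI,
) -> BandPowerSeries:
    """Mean over band frequencies, then ROI channels -> trials x time.

    NaN (masked) samples propagate.  Averaging over trials within
    condition is left to the caller, which holds the trial metadata.
    """
    lo, hi = band
    fsel = (tfr.freqs_hz >= lo) & (tfr.freqs_hz <= hi)
    if not fsel.any():
        raise ValueError(f"band {band} outside frequency grid")
    csel = tfr.channel_index(roi)
    series = tfr.power[:, csel][:, :, fsel, :].mean(axis=2).mean(axis=1)
    return BandPowerSeries(
        power=series,
        times_s=tfr.times_s,
        band_hz=(float(lo), float(hi)),
        roi=tuple(roi),
        trials=tfr.trials,
    )


def difference_spectrogram(self_avg: np.ndarray, stim_avg: np.ndarray) -> np.ndarray:
    """Elementwise self minus stim grand-average power; NaN propagates."""
    self_avg, stim_avg = np.asarray(self_avg, float), np.asarray(stim_avg, float)
    if self_avg.shape != stim_avg.shape:
        raise ValueError("spectrogram grids do not match")
    return self_avg - stim_avg


def shared_color_axis(
    power_maps: Sequence[np.ndarray],
    freqs_hz: np.ndarray,
    times_s: np.ndarray,
    band: tuple = BETA_BAND,
    window_s: tuple = (-1.0, 0.5),
    pct: tuple = (2.0, 98.0),
) -> tuple[float, float]:
    """Display limits from pooled percentiles of valid in-band values.

    Percentiles use linear interpolation between order statistics.
    """
    fsel = (np.asarray(freqs_hz) >= band[0]) & (np.asarray(freqs_hz) <= band[1])
    tsel = (np.asarray(times_s) >= window_s[0]) & (np.asarray(times_s) <= window_s[1])
    pool = []
    for m in power_maps:
        sub = np.asarray(m, float)[fsel][:, tsel]
        pool.append(sub[np.isfinite(sub)])
    pooled = np.concatenate(pool) if pool else np.array([])
    if pooled.size == 0:
        raise ValueError("no valid values to pool for the color axis")
    lo, hi = np.percentile(pooled, pct, method="linear")
    return float(lo), float(hi)
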